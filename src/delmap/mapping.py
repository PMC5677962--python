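"""Sliding-window prevalence mapping along a deletion locus.

The method: for each clinical feature, prevalence among informative
deletion carriers is profiled in overlapping windows (default 1.5 Mb every
50 kb) along the locus, where a carrier belongs to a window iff the
proximal breakpoint of its locus deletion lies in the window.  The
candidate region spans the first to the last window whose prevalence
strictly exceeds the cohort-wide (global) prevalence.  Enrichment of the
feature among carriers whose deletion starts inside the region is then
tested with Fisher's exact machinery (two-sided exact p, conditional-MLE
odds ratio with exact conditional CI), and an empirical "sampling" p-value
is obtained by re-shuffling feature labels among informative carriers and
re-running the whole derivation per permutation, counting permutations
whose enrichment odds ratio strictly exceeds the observed one.

Two odds-ratio estimators coexist deliberately: the headline estimate is
the conditional MLE under the noncentral hypergeometric likelihood (with
exact conditional confidence bounds, +infinity on boundary tables), while
permutation comparisons use the cross-product (sample) OR with a
Haldane-Anscombe +0.5 correction on zero cells so that boundary
permutations remain finite and comparable.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.optimize import brentq

from .cohort import (
    Cohort,
    GenomicInterval,
    GeneModel,
    TriState,
    UndefinedStatisticError,
    ValidationError,
    select_mapping_set,
)

__all__ = [
    "MappingParams",
    "WindowStat",
    "CandidateRegion",
    "AssociationResult",
    "MappingResult",
    "Fisher2x2",
    "global_prevalence",
    "window_profile",
    "extract_candidate_region",
    "fisher_exact_2x2",
    "fisher_enrichment",
    "sampling_pvalue",
    "map_feature",
    "candidate_genes",
]


@dataclass(frozen=True)
class MappingParams:
    """Tuning knobs of the window/permutation machinery.

    Defaults are the analysis' standard operating point: 1.5 Mb windows
    sliding by 50 kb, windows with fewer than 3 informative carriers
    masked, 1000 label permutations.
    """

    window_size: int = 1_500_000
    step: int = 50_000
    min_informative: int = 3
    n_permutations: int = 1000
    rng_seed: int = 0
    #: "extent": region spans from the start of the first passing window to
    #: the end of the last; "anchor": spans the passing window anchors only.
    region_mode: str = "extent"
    #: "start": a carrier is in-region iff its deletion breakpoint lies in
    #: the region; "span": iff its deletion overlaps the region.
    membership: str = "start"
    #: use (k+1)/(N+1) instead of k/N for the empirical p-value
    small_sample_correction: bool = False
    #: re-test the fixed observed region per permutation instead of
    #: re-deriving the candidate region
    fixed_region: bool = False

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step > 0):
            raise ValidationError("require window_size >= step > 0")
        if self.min_informative < 1:
            raise ValidationError("min_informative must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.region_mode not in ("extent", "anchor"):
            raise ValidationError(f"unknown region_mode {self.region_mode!r}")
        if self.membership not in ("start", "span"):
            raise ValidationError(f"unknown membership {self.membership!r}")


@dataclass(frozen=True)
class WindowStat:
    window: GenomicInterval
    n_informative: int
    n_present: int
    masked: bool
    prevalence: float  # NaN when masked
    se: float  # NaN when masked


@dataclass(frozen=True)
class CandidateRegion:
    feature: str
    region: GenomicInterval
    n_windows_passing: int


@dataclass(frozen=True)
class Fisher2x2:
    a: int
    b: int
    c: int
    d: int
    p: float
    or_cmle: float  # conditional-MLE odds ratio; may be 0, +inf or NaN
    ci_low: float
    ci_high: float
    or_sample: float  # cross-product OR, Haldane-corrected on zero cells


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    region: GenomicInterval
    a: int  # in-region, feature present
    b: int  # in-region, feature absent
    c: int  # out-of-region, present
    d: int  # out-of-region, absent
    regional_prevalence: float
    global_prevalence: float
    global_se: float
    n_informative: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    or_sample: float
    fisher_p: float
    sampling_p: float | None = None
    n_permutations: int | None = None
    rng_seed: int | None = None


@dataclass(frozen=True)
class MappingResult:
    feature: str
    profile: tuple[WindowStat, ...]
    candidate: CandidateRegion | None
    association: AssociationResult | None
    global_prevalence: float
    global_se: float
    n_informative: int


# ---------------------------------------------------------------------------
# Carrier arrays

def _carrier_arrays(cohort: Cohort, feature: str):
    """Arrays over informative locus-deletion carriers, sorted by patient id.

    Sorting makes every downstream statistic invariant to the input order
    of patients, including the seeded permutation stream.
    """
    rows = []
    for p in cohort:
        bp = p.locus_del_start
        if bp is None:
            dels = p.locus_deletions(cohort.locus)
            if not dels:
                continue
            bp = min(c.interval.start for c in dels)
        st = p.phenotypes.values.get(feature, TriState.UNKNOWN)
        if st is TriState.UNKNOWN:
            continue
        del_end = max(
            c.interval.end for c in p.locus_deletions(cohort.locus)
        )
        rows.append((p.id, bp, del_end, st is TriState.PRESENT))
    rows.sort(key=lambda r: r[0])
    ids = [r[0] for r in rows]
    bp = np.array([r[1] for r in rows], dtype=np.int64)
    de = np.array([r[2] for r in rows], dtype=np.int64)
    present = np.array([r[3] for r in rows], dtype=bool)
    return ids, bp, de, present


def global_prevalence(cohort: Cohort, feature: str) -> tuple[float, float, int]:
    """Feature prevalence over all informative locus-deletion carriers.

    Returns (prevalence, standard error of the proportion, n_informative)
    with se = sqrt(p(1-p)/n).
    """
    _, _, _, present = _carrier_arrays(cohort, feature)
    n = present.size
    if n == 0:
        raise UndefinedStatisticError(f"no informative deletion carrier for {feature!r}")
    p = present.sum() / n
    se = math.sqrt(p * (1.0 - p) / n)
    return float(p), se, int(n)


# ---------------------------------------------------------------------------
# Window profile

def window_grid(locus: GenomicInterval, params: MappingParams):
    """Window starts/ends: anchors every `step` from locus.start while the
    anchor is inside the locus; windows truncate at the locus end."""
    starts = np.arange(locus.start, locus.end, params.step, dtype=np.int64)
    ends = np.minimum(starts + params.window_size, locus.end)
    return starts, ends


def window_profile(
    cohort: Cohort, feature: str, params: MappingParams = MappingParams()
) -> list[WindowStat]:
    """Sliding-window prevalence of `feature` along the cohort locus.

    A carrier belongs to a window iff its deletion proximal breakpoint lies
    in [window start, window end).  Windows with fewer informative carriers
    than params.min_informative are emitted masked (prevalence/se NaN).
    """
    _, bp, _, present = _carrier_arrays(cohort, feature)
    starts, ends = window_grid(cohort.locus, params)
    inw = (bp[None, :] >= starts[:, None]) & (bp[None, :] < ends[:, None])
    n_inf = inw.sum(axis=1)
    n_pres = (inw & present[None, :]).sum(axis=1)
    out: list[WindowStat] = []
    for s, e, ni, npr in zip(starts, ends, n_inf, n_pres):
        masked = ni < params.min_informative
        if masked:
            prev = se = math.nan
        else:
            prev = npr / ni
            se = math.sqrt(prev * (1.0 - prev) / ni)
        out.append(
            WindowStat(
                window=GenomicInterval(cohort.locus.chrom, int(s), int(e)),
                n_informative=int(ni),
                n_present=int(npr),
                masked=bool(masked),
                prevalence=prev,
                se=se,
            )
        )
    return out


def extract_candidate_region(
    profile: Sequence[WindowStat],
    global_prev: float,
    feature: str = "feature",
    region_mode: str = "extent",
    step: int | None = None,
) -> CandidateRegion | None:
    """Min-max span of windows whose prevalence strictly exceeds global.

    "extent" mode spans from the start of the first passing window to the
    end of the last passing window; "anchor" mode spans the passing window
    anchors (plus one step so a single passing window is representable).
    Non-contiguous passing windows are spanned, literal min-max.  Returns
    None when no window passes.
    """
    passing = [w for w in profile if not w.masked and w.prevalence > global_prev]
    if not passing:
        return None
    chrom = passing[0].window.chrom
    if region_mode == "extent":
        region = GenomicInterval(chrom, passing[0].window.start, passing[-1].window.end)
    elif region_mode == "anchor":
        if step is None:
            step = (
                profile[1].window.start - profile[0].window.start
                if len(profile) > 1
                else passing[0].window.length
            )
        region = GenomicInterval(
            chrom, passing[0].window.start, passing[-1].window.start + step
        )
    else:
        raise ValidationError(f"unknown region_mode {region_mode!r}")
    return CandidateRegion(feature=feature, region=region, n_windows_passing=len(passing))


# ---------------------------------------------------------------------------
# Fisher exact machinery

def _log_comb(n: float, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _support(m1: int, m2: int, n1: int) -> np.ndarray:
    lo = max(0, n1 - m2)
    hi = min(m1, n1)
    return np.arange(lo, hi + 1)


def _cond_log_like(k: np.ndarray, m1: int, m2: int, n1: int, log_psi: float) -> np.ndarray:
    return _log_comb(m1, k) + _log_comb(m2, n1 - k) + k * log_psi


def _cmle(a: int, m1: int, m2: int, n1: int) -> float:
    """Conditional MLE of the odds ratio: solves E_psi[X] = a."""
    k = _support(m1, m2, n1)

    def mean_minus_a(log_psi: float) -> float:
        lw = _cond_log_like(k, m1, m2, n1, log_psi)
        w = np.exp(lw - lw.max())
        return float((k * w).sum() / w.sum()) - a

    lo, hi = -40.0, 40.0
    if mean_minus_a(lo) > 0 or mean_minus_a(hi) < 0:  # numerically at boundary
        return 0.0 if mean_minus_a(lo) > 0 else math.inf
    return math.exp(brentq(mean_minus_a, lo, hi, xtol=1e-12, rtol=1e-14))


def _tail_root(
    a: int, m1: int, m2: int, n1: int, alpha: float, upper_tail: bool
) -> float:
    """psi such that P_psi(X >= a) = alpha (upper_tail) or P_psi(X <= a) = alpha."""
    k = _support(m1, m2, n1)
    sel = k >= a if upper_tail else k <= a

    def tail_minus_alpha(log_psi: float) -> float:
        lw = _cond_log_like(k, m1, m2, n1, log_psi)
        return math.exp(logsumexp(lw[sel]) - logsumexp(lw)) - alpha

    lo, hi = -45.0, 45.0
    flo, fhi = tail_minus_alpha(lo), tail_minus_alpha(hi)
    if flo * fhi > 0:  # tail never crosses alpha within range -> boundary
        return 0.0 if (flo < 0 if upper_tail else flo > 0) else math.inf
    return math.exp(brentq(tail_minus_alpha, lo, hi, xtol=1e-12, rtol=1e-14))


def haldane_sample_or(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio with +0.5 on all cells if any cell is zero."""
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> Fisher2x2:
    """Two-sided Fisher exact test with conditional-MLE OR and exact CI.

    The two-sided p sums hypergeometric point probabilities of all tables
    (with the observed margins) at most as probable as the observed one,
    with the customary (1+1e-7) relative tolerance on the comparison.  The
    OR point estimate is the conditional MLE under the noncentral
    hypergeometric likelihood; confidence bounds invert the exact
    conditional tails at alpha/2 per side.  Boundary tables give OR 0 or
    +inf with the corresponding one-sided bound.  Degenerate margins (an
    empty row or column) give p = 1 and an undefined (NaN) OR.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell count")
    m1, m2, n1 = a + b, c + d, a + c
    k = _support(m1, m2, n1)
    if k.size <= 1:  # degenerate margins: only one table possible
        return Fisher2x2(a, b, c, d, 1.0, math.nan, 0.0, math.inf,
                         haldane_sample_or(a, b, c, d))
    logpmf = _cond_log_like(k, m1, m2, n1, 0.0)
    logpmf -= logsumexp(logpmf)
    pmf = np.exp(logpmf)
    p_obs = pmf[a - k[0]]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)

    if a == k[-1]:
        or_cmle, ci_high = math.inf, math.inf
    else:
        or_cmle = None
        ci_high = _tail_root(a, m1, m2, n1, alpha / 2, upper_tail=False)
    if a == k[0]:
        or_cmle, ci_low = 0.0, 0.0
    else:
        ci_low = _tail_root(a, m1, m2, n1, alpha / 2, upper_tail=True)
    if or_cmle is None:
        or_cmle = _cmle(a, m1, m2, n1)
    return Fisher2x2(a, b, c, d, p, or_cmle, ci_low, ci_high,
                     haldane_sample_or(a, b, c, d))


def _region_counts(
    bp: np.ndarray,
    del_end: np.ndarray,
    present: np.ndarray,
    region: GenomicInterval,
    membership: str,
) -> tuple[int, int, int, int]:
    if membership == "start":
        inr = (bp >= region.start) & (bp < region.end)
    else:  # span: deletion overlaps the region
        inr = (bp < region.end) & (del_end > region.start)
    a = int((inr & present).sum())
    b = int((inr & ~present).sum())
    c = int((~inr & present).sum())
    d = int((~inr & ~present).sum())
    return a, b, c, d


def fisher_enrichment(
    cohort: Cohort,
    feature: str,
    region: GenomicInterval,
    params: MappingParams = MappingParams(),
) -> AssociationResult:
    """Enrichment of the feature among carriers with deletion start in-region.

    2x2 over informative carriers: deletion start in/out of region x
    feature present/absent (membership switchable to deletion-spans-region
    via params.membership).  sampling_p is left unset here.
    """
    if not cohort.locus.contains(region):
        raise ValidationError(f"region {region} outside locus {cohort.locus}")
    _, bp, de, present = _carrier_arrays(cohort, feature)
    if present.size == 0:
        raise UndefinedStatisticError(f"no informative carrier for {feature!r}")
    a, b, c, d = _region_counts(bp, de, present, region, params.membership)
    fr = fisher_exact_2x2(a, b, c, d)
    gp, gse, n = global_prevalence(cohort, feature)
    return AssociationResult(
        feature=feature,
        region=region,
        a=a, b=b, c=c, d=d,
        regional_prevalence=a / (a + b) if (a + b) else math.nan,
        global_prevalence=gp,
        global_se=gse,
        n_informative=n,
        odds_ratio=fr.or_cmle,
        ci_low=fr.ci_low,
        ci_high=fr.ci_high,
        or_sample=fr.or_sample,
        fisher_p=fr.p,
    )


# ---------------------------------------------------------------------------
# Permutation engine

def _permutation_ors(
    bp: np.ndarray,
    del_end: np.ndarray,
    labels: np.ndarray,  # (n_carriers, P) boolean
    locus: GenomicInterval,
    params: MappingParams,
    fixed_region: GenomicInterval | None = None,
) -> np.ndarray:
    """Haldane sample OR per permutation column, 0 where no region emerges.

    Vectorised re-run of the full derivation (window profile -> candidate
    region -> 2x2) for every label column.  Window informativeness and the
    global prevalence depend only on margins, hence are shared.
    """
    n, P = labels.shape
    gp = labels[:, 0].sum() / n  # label counts preserved by permutation
    starts, ends = window_grid(locus, params)
    W = (bp[None, :] >= starts[:, None]) & (bp[None, :] < ends[:, None])
    n_inf = W.sum(axis=1)
    unmasked = n_inf >= params.min_informative
    if fixed_region is not None:
        rs = np.full(P, fixed_region.start, dtype=np.int64)
        re_ = np.full(P, fixed_region.end, dtype=np.int64)
        has_region = np.ones(P, dtype=bool)
    else:
        n_pres = W.astype(np.int64) @ labels.astype(np.int64)  # (nwin, P)
        with np.errstate(invalid="ignore", divide="ignore"):
            prev = n_pres / n_inf[:, None]
        passing = unmasked[:, None] & (prev > gp)
        has_region = passing.any(axis=0)
        first = passing.argmax(axis=0)
        last = passing.shape[0] - 1 - passing[::-1].argmax(axis=0)
        if params.region_mode == "extent":
            rs, re_ = starts[first], ends[last]
        else:  # anchor
            rs, re_ = starts[first], starts[last] + params.step
    if params.membership == "start":
        inr = (bp[:, None] >= rs[None, :]) & (bp[:, None] < re_[None, :])
    else:
        inr = (bp[:, None] < re_[None, :]) & (del_end[:, None] > rs[None, :])
    a = (inr & labels).sum(axis=0).astype(float)
    b = (inr & ~labels).sum(axis=0).astype(float)
    c = ((~inr) & labels).sum(axis=0).astype(float)
    d = ((~inr) & ~labels).sum(axis=0).astype(float)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    num = np.where(zero, (a + 0.5) * (d + 0.5), a * d)
    den = np.where(zero, (b + 0.5) * (c + 0.5), b * c)
    ors = num / den
    ors[~has_region] = 0.0
    return ors


def sampling_pvalue(
    cohort: Cohort,
    feature: str,
    observed_or: float,
    params: MappingParams = MappingParams(),
    exact: bool = False,
    fixed_region: GenomicInterval | None = None,
) -> float:
    """Empirical p-value from label reshuffling among informative carriers.

    Each permutation redraws the assignment of the observed present/absent
    labels to the informative carriers (the missingness pattern and the
    number of present labels are preserved exactly), re-derives the
    candidate region and its enrichment OR, and the p-value is the
    fraction of permutations whose Haldane-corrected sample OR strictly
    exceeds `observed_or`.  `exact=True` enumerates every distinct label
    assignment instead of sampling (small cohorts only).
    """
    _, bp, de, present = _carrier_arrays(cohort, feature)
    n = present.size
    if n == 0:
        raise UndefinedStatisticError(f"no informative carrier for {feature!r}")
    k = int(present.sum())
    region = fixed_region
    if params.fixed_region and region is None:
        gp = k / n
        prof = window_profile(cohort, feature, params)
        cand = extract_candidate_region(prof, gp, feature, params.region_mode, params.step)
        if cand is None:
            raise UndefinedStatisticError("fixed_region mode but no observed region")
        region = cand.region
    if exact:
        n_arr = math.comb(n, k)
        if n_arr > 200_000:
            raise ValidationError(f"exact enumeration infeasible: {n_arr} arrangements")
        labels = np.zeros((n, n_arr), dtype=bool)
        for j, pos in enumerate(itertools.combinations(range(n), k)):
            labels[list(pos), j] = True
        ors = _permutation_ors(bp, de, labels, cohort.locus, params, region)
        return float((ors > observed_or).sum() / n_arr)
    P = params.n_permutations
    rng = np.random.default_rng(params.rng_seed)
    base = np.tile(present, (P, 1))
    labels = rng.permuted(base, axis=1).T  # (n, P)
    ors = _permutation_ors(bp, de, labels, cohort.locus, params, region)
    count = int((ors > observed_or).sum())
    if params.small_sample_correction:
        return (count + 1) / (P + 1)
    return count / P


def _feature_subseed(seed: int, feature: str) -> int:
    ss = np.random.SeedSequence([seed, zlib.crc32(feature.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


def map_feature(
    cohort: Cohort,
    feature: str,
    params: MappingParams = MappingParams(),
) -> MappingResult:
    """Full mapping of one feature: profile, candidate region, association.

    The cohort is reduced to the mapping set (QC-pass locus-deletion
    carriers) if not already; the permutation stream is seeded from
    (params.rng_seed, feature) so feature order never matters.
    """
    if any(p.locus_del_start is None for p in cohort):
        cohort = select_mapping_set(cohort)
    gp, gse, n = global_prevalence(cohort, feature)
    profile = tuple(window_profile(cohort, feature, params))
    cand = extract_candidate_region(profile, gp, feature, params.region_mode, params.step)
    assoc = None
    if cand is not None:
        assoc = fisher_enrichment(cohort, feature, cand.region, params)
        sub = _feature_subseed(params.rng_seed, feature)
        sp = sampling_pvalue(
            cohort, feature, assoc.or_sample, replace(params, rng_seed=sub)
        )
        assoc = replace(
            assoc, sampling_p=sp, n_permutations=params.n_permutations, rng_seed=sub
        )
    return MappingResult(
        feature=feature,
        profile=profile,
        candidate=cand,
        association=assoc,
        global_prevalence=gp,
        global_se=gse,
        n_informative=n,
    )


# ---------------------------------------------------------------------------
# Candidate genes

def candidate_genes(region: GenomicInterval, genes: Sequence[GeneModel]):
    """Genes overlapping the region, ranked for haploinsufficiency.

    Every gene overlapping by >= 1 base is included; class "contained" if
    the gene lies wholly inside the region, else "boundary".  Ranking:
    ascending HI rank, then descending pLI, missing values last.
    """
    import pandas as pd

    rows = []
    for g in genes:
        if not g.interval.overlaps(region):
            continue
        rows.append(
            {
                "symbol": g.symbol,
                "hi_rank": g.hi_rank,
                "pli": g.pli,
                "overlap_class": "contained" if region.contains(g.interval) else "boundary",
            }
        )
    df = pd.DataFrame(rows, columns=["symbol", "hi_rank", "pli", "overlap_class"])
    if df.empty:
        return df
    hi_key = df["hi_rank"].fillna(math.inf)
    pli_key = (-df["pli"]).fillna(math.inf)
    order = np.lexsort((df["symbol"].to_numpy(), pli_key.to_numpy(), hi_key.to_numpy()))
    return df.iloc[order].reset_index(drop=True)
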