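"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — math.comb
enumeration, greedy agglomeration, plain-Python window loops — and shares
no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np

# ---------------------------------------------------------------------------
# Fisher exact: exhaustive hypergeometric enumeration


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p: sum of point probabilities <= observed (fixed margins)."""
    m1, m2, n1 = a + b, c + d, a + c
    N = m1 + m2
    if N == 0:
        return 1.0
    denom = comb(N, n1)
    lo, hi = max(0, n1 - m2), min(m1, n1)
    probs = {k: comb(m1, k) * comb(m2, n1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def _log_weights(m1: int, m2: int, n1: int, log_psi: float) -> tuple[list[int], list[float]]:
    lo, hi = max(0, n1 - m2), min(m1, n1)
    ks = list(range(lo, hi + 1))
    lw = [math.log(comb(m1, k)) + math.log(comb(m2, n1 - k)) + k * log_psi for k in ks]
    return ks, lw


def _norm_weights(lw: list[float]) -> list[float]:
    m = max(lw)
    w = [math.exp(x - m) for x in lw]
    s = sum(w)
    return [x / s for x in w]


def _cond_loglik(a: int, m1: int, m2: int, n1: int, log_psi: float) -> float:
    ks, lw = _log_weights(m1, m2, n1, log_psi)
    m = max(lw)
    return lw[ks.index(a)] - (m + math.log(sum(math.exp(x - m) for x in lw)))


def cmle_oracle(a: int, b: int, c: int, d: int) -> float:
    """Conditional MLE by golden-section maximization of the likelihood."""
    m1, m2, n1 = a + b, c + d, a + c
    lo_k, hi_k = max(0, n1 - m2), min(m1, n1)
    if lo_k == hi_k:
        return math.nan
    if a == hi_k:
        return math.inf
    if a == lo_k:
        return 0.0
    gr = (math.sqrt(5) - 1) / 2
    lo, hi = -40.0, 40.0
    for _ in range(200):
        x1 = hi - gr * (hi - lo)
        x2 = lo + gr * (hi - lo)
        if _cond_loglik(a, m1, m2, n1, x1) < _cond_loglik(a, m1, m2, n1, x2):
            lo = x1
        else:
            hi = x2
    return math.exp((lo + hi) / 2)


def _tail(a: int, m1: int, m2: int, n1: int, log_psi: float, upper: bool) -> float:
    ks, lw = _log_weights(m1, m2, n1, log_psi)
    w = _norm_weights(lw)
    return sum(wi for k, wi in zip(ks, w) if (k >= a if upper else k <= a))


def exact_ci_oracle(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact conditional CI by bisection on the noncentral tails."""
    m1, m2, n1 = a + b, c + d, a + c
    lo_k, hi_k = max(0, n1 - m2), min(m1, n1)
    if lo_k == hi_k:
        return 0.0, math.inf

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return math.exp((lo + hi) / 2)

    if a == lo_k:
        ci_low = 0.0
    else:
        # P_psi(X >= a) grows with psi; find where it crosses alpha/2
        ci_low = bisect(lambda lp: _tail(a, m1, m2, n1, lp, True) - alpha / 2, -45.0, 45.0)
    if a == hi_k:
        ci_high = math.inf
    else:
        ci_high = bisect(lambda lp: (alpha / 2) - _tail(a, m1, m2, n1, lp, False), -45.0, 45.0)
    return ci_low, ci_high


# ---------------------------------------------------------------------------
# Sliding-window mapping: plain-Python re-derivation for tiny cohorts


def haldane_or_oracle(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    return a * d / (b * c)


def mapping_or_oracle(
    bps: list[int],
    labels: list[bool],
    locus_start: int,
    locus_end: int,
    window: int = 1_500_000,
    step: int = 50_000,
    min_informative: int = 3,
) -> float:
    """Enrichment OR of the min-max candidate region, 0 if none emerges."""
    n = len(bps)
    gp = sum(labels) / n
    passing: list[tuple[int, int]] = []
    g = locus_start
    while g < locus_end:
        e = min(g + window, locus_end)
        idx = [i for i in range(n) if g <= bps[i] < e]
        if len(idx) >= min_informative:
            prev = sum(labels[i] for i in idx) / len(idx)
            if prev > gp:
                passing.append((g, e))
        g += step
    if not passing:
        return 0.0
    rs, re = passing[0][0], passing[-1][1]
    a = sum(1 for i in range(n) if rs <= bps[i] < re and labels[i])
    b = sum(1 for i in range(n) if rs <= bps[i] < re and not labels[i])
    c = sum(1 for i in range(n) if not (rs <= bps[i] < re) and labels[i])
    d = n - a - b - c
    return haldane_or_oracle(a, b, c, d)


def permutation_p_oracle(
    bps: list[int],
    labels: list[bool],
    observed_or: float,
    locus_start: int,
    locus_end: int,
    **window_kwargs,
) -> float:
    """Exhaustive label-permutation p over all distinct assignments."""
    n, k = len(labels), sum(labels)
    total = greater = 0
    for pos in itertools.combinations(range(n), k):
        perm = [i in pos for i in range(n)]
        total += 1
        if mapping_or_oracle(bps, perm, locus_start, locus_end, **window_kwargs) > observed_or:
            greater += 1
    return greater / total


# ---------------------------------------------------------------------------
# Ward agglomeration: greedy brute force over all merges


def ward_merges_oracle(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Greedy Ward.D2 agglomeration evaluating every candidate merge.

    Merge height is sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||,
    i.e. the square-rooted doubled within-cluster variance increase.
    """
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                A, B = X[clusters[i]], X[clusters[j]]
                na, nb = len(A), len(B)
                d = math.sqrt(2 * na * nb / (na + nb)) * float(
                    np.linalg.norm(A.mean(axis=0) - B.mean(axis=0))
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), d))
        merged = clusters[i] + clusters[j]
        clusters = [c for k2, c in enumerate(clusters) if k2 not in (i, j)] + [merged]
    return merges


def linkage_merges(Z: np.ndarray, n: int) -> list[tuple[frozenset, frozenset, float]]:
    """Decode a scipy linkage matrix into (set, set, height) merge steps."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (i, j, h, _) in enumerate(Z):
        a, b = members[int(i)], members[int(j)]
        out.append((a, b, float(h)))
        members[n + step] = a | b
    return out
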