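"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates a terminal-deletion syndrome cohort: each carrier
has a deletion running from a variable proximal breakpoint to the end of
the locus chromosome (sizes 45.8 kb to 9.1 Mb by default), a planted risk
segment turns clinical features on with penetrance p_in for carriers whose
deletion overlaps the segment and p_out otherwise, feature status is
masked to unknown completely at random, and additional genome-wide CNVs
are scattered over a simulated neuropsychiatric (NP) gene panel.  The
planted truth (segments, penetrances, per-patient carrier flags) is
emitted alongside the cohort so recovery can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import (
    CNVCall,
    Cohort,
    DEFAULT_LOCUS,
    GeneModel,
    GenomicInterval,
    Patient,
    PhenotypeProfile,
    TriState,
    ValidationError,
    write_cohort,
)

__all__ = [
    "FeatureSpec",
    "SimulationParams",
    "PlantedTruth",
    "simulate_cohort",
    "simulate_gene_annotation",
    "write_simulation",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One simulated binary feature.

    planted_segment None makes the feature pure noise at rate p_out.
    Null scenarios set p_in == p_out explicitly.
    """

    name: str
    planted_segment: GenomicInterval | None
    p_in: float
    p_out: float
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.p_in, self.p_out, self.missing_rate):
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"rate {r} outside [0,1] for {self.name}")


def _default_features() -> tuple[FeatureSpec, ...]:
    # study-scale conditions: a 2 Mb risk segment with strong but
    # incomplete penetrance against a common background rate, planted so
    # that roughly one carrier in five has a deletion reaching it (the
    # in-region fraction real 22q13 mapping cohorts exhibit)
    return (
        FeatureSpec(
            name="absence_of_speech",
            planted_segment=GenomicInterval("chr22", 45_000_000, 47_000_000),
            p_in=0.85,
            p_out=0.30,
            missing_rate=0.10,
        ),
    )


@dataclass(frozen=True)
class SimulationParams:
    n_patients: int = 70
    locus: GenomicInterval = DEFAULT_LOCUS
    deletion_size_range: tuple[int, int] = (45_800, 9_100_000)
    #: right-skewed sizes are the realistic default: most terminal
    #: deletions are small, so breakpoint density rises toward the telomere
    size_distribution: str = "exponential-truncated"  # or "uniform"
    features: tuple[FeatureSpec, ...] = field(default_factory=_default_features)
    dup_fraction: float = 0.08
    mosaic_rate: float = 0.03
    np_cnv_rate: float = 1.0  # Poisson mean additional NP-hitting CNVs / patient
    n_np_genes: int = 120
    #: fraction of deletions drawn interstitial (two internal breakpoints)
    #: instead of terminal; used to probe start-vs-span membership rules
    interstitial_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.deletion_size_range
        if not (0 < lo <= hi):
            raise ValidationError("bad deletion_size_range")
        if hi > self.locus.length:
            raise ValidationError("max deletion size exceeds locus length")
        if self.size_distribution not in ("uniform", "exponential-truncated"):
            raise ValidationError(f"unknown size distribution {self.size_distribution!r}")
        for r in (self.dup_fraction, self.mosaic_rate, self.interstitial_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"rate {r} outside [0,1]")
        if self.n_patients < 1 or self.n_np_genes < 1:
            raise ValidationError("n_patients and n_np_genes must be >= 1")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted with a simulated cohort."""

    features: dict[str, dict]  # name -> {segment, p_in, p_out, missing_rate}
    breakpoints: dict[str, int | None]  # patient -> proximal DEL breakpoint
    carrier_flags: dict[str, dict[str, bool]]  # feature -> patient -> risk carrier

    def to_json(self) -> str:
        def seg(s):
            return None if s is None else [s.chrom, s.start, s.end]

        payload = {
            "features": {
                n: {**{k: v for k, v in d.items() if k != "segment"},
                    "segment": seg(d["segment"])}
                for n, d in self.features.items()
            },
            "breakpoints": self.breakpoints,
            "carrier_flags": self.carrier_flags,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _draw_sizes(params: SimulationParams, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = params.deletion_size_range
    if params.size_distribution == "uniform":
        return rng.integers(lo, hi + 1, size=n)
    # exponential truncated to [lo, hi]; scale = a third of the span keeps
    # most mass at small deletions, as observed size distributions are skewed
    scale = (hi - lo) / 3.0
    u = rng.random(n)
    cdf_hi = 1.0 - math.exp(-(hi - lo) / scale)
    return (lo + (-scale * np.log(1.0 - u * cdf_hi))).astype(np.int64)


def simulate_gene_annotation(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Non-overlapping gene models with 2-10 exons scattered over autosomes.

    Roughly 1 in 6 generated genes is a non-panel decoy (is_np_gene False)
    so exon-overlap filtering is exercised; HI/pLI are random with ~10%
    missing.  Genes never fall on the locus chromosome, keeping panel hits
    cleanly separable from the defining rearrangement.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed + 1)
    chroms = [f"chr{i}" for i in range(1, 22) if f"chr{i}" != params.locus.chrom]
    n_total = params.n_np_genes + max(1, params.n_np_genes // 6)
    genes: list[GeneModel] = []
    cursor: dict[str, int] = {c: 1_000_000 for c in chroms}
    for gi in range(n_total):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        gap = int(rng.integers(50_000, 500_000))
        start = cursor[chrom] + gap
        length = int(rng.integers(5_000, 200_000))
        end = start + length
        cursor[chrom] = end
        n_ex = int(rng.integers(2, 11))
        # cut the gene body into 2*n_ex slots; odd slots become exons
        bounds = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 1, replace=False))
        bounds = np.concatenate([[0], bounds, [length]])
        exons = tuple(
            GenomicInterval(chrom, start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
            for i in range(n_ex)
        )
        hi = float(rng.uniform(0, 100)) if rng.random() > 0.1 else math.nan
        pli = float(rng.uniform(0, 1)) if rng.random() > 0.1 else math.nan
        genes.append(
            GeneModel(
                symbol=f"SIMG{gi:04d}",
                interval=GenomicInterval(chrom, start, end),
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
                hi_rank=hi,
                pli=pli,
                is_np_gene=gi < params.n_np_genes,
            )
        )
    return genes


def simulate_cohort(
    params: SimulationParams, genes: list[GeneModel] | None = None
) -> tuple[Cohort, PlantedTruth]:
    """Draw a cohort and its planted truth; same seed, same cohort, always.

    Deletions are terminal ([locus.end - size, locus.end)) unless drawn
    interstitial; a patient is a risk carrier for a feature iff its
    deletion overlaps the planted segment; feature presence is Bernoulli
    p_in / p_out, then masked to unknown at the feature's missing rate.
    Additional CNVs (Poisson per patient) are centred on random exons of
    the simulated NP panel.
    """
    rng = np.random.default_rng(params.rng_seed)
    if genes is None:
        genes = simulate_gene_annotation(params)
    np_genes = [g for g in genes if g.is_np_gene]
    locus = params.locus

    n = params.n_patients
    is_dup = rng.random(n) < params.dup_fraction
    sizes = _draw_sizes(params, rng, n)
    interstitial = rng.random(n) < params.interstitial_fraction
    mosaic = rng.random(n) < params.mosaic_rate
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    inh = rng.choice(
        ["de_novo", "maternal", "paternal", "unknown"], size=n, p=[0.65, 0.1, 0.1, 0.15]
    )

    patients: list[Patient] = []
    breakpoints: dict[str, int | None] = {}
    carrier_flags: dict[str, dict[str, bool]] = {f.name: {} for f in params.features}

    for i in range(n):
        pid = f"S{i + 1:03d}"
        size = int(sizes[i])
        if interstitial[i]:
            slack = locus.length - size
            offset = int(rng.integers(1, max(2, slack)))  # keep distal end internal
            start = locus.end - size - offset
        else:
            start = locus.end - size
        interval = GenomicInterval(locus.chrom, start, min(start + size, locus.end))
        main = CNVCall(
            patient_id=pid,
            interval=interval,
            dosage_type="DUP" if is_dup[i] else "DEL",
            inheritance=str(inh[i]),
            mosaic=bool(mosaic[i]),
            mechanism="simple",
        )
        cnvs = [main]
        for _ in range(int(rng.poisson(params.np_cnv_rate))):
            g = np_genes[int(rng.integers(0, len(np_genes)))]
            e = g.exons[int(rng.integers(0, len(g.exons)))]
            pad_l = int(rng.integers(0, 50_000))
            pad_r = int(rng.integers(0, 50_000))
            cnvs.append(
                CNVCall(
                    patient_id=pid,
                    interval=GenomicInterval(
                        e.chrom, max(0, e.start - pad_l), e.end + pad_r
                    ),
                    dosage_type="DEL" if rng.random() < 0.5 else "DUP",
                    inheritance="unknown",
                    mosaic=False,
                    mechanism="simple",
                )
            )

        pheno: dict[str, TriState] = {}
        is_del = main.dosage_type == "DEL"
        breakpoints[pid] = interval.start if is_del else None
        for f in params.features:
            carrier = bool(
                is_del
                and f.planted_segment is not None
                and interval.overlaps(f.planted_segment)
            )
            carrier_flags[f.name][pid] = carrier
            p = f.p_in if carrier else f.p_out
            status = TriState.PRESENT if rng.random() < p else TriState.ABSENT
            if rng.random() < f.missing_rate:
                status = TriState.UNKNOWN
            pheno[f.name] = status

        patients.append(
            Patient(
                id=pid,
                sex=str(sexes[i]),
                center="SIM",
                array_qc_pass=True,
                phenotypes=PhenotypeProfile(pheno),
                cnvs=tuple(cnvs),
            )
        )

    truth = PlantedTruth(
        features={
            f.name: {
                "segment": f.planted_segment,
                "p_in": f.p_in,
                "p_out": f.p_out,
                "missing_rate": f.missing_rate,
            }
            for f in params.features
        },
        breakpoints=breakpoints,
        carrier_flags=carrier_flags,
    )
    return Cohort(tuple(patients), locus=locus), truth


# ---------------------------------------------------------------------------
# File emission

def write_gene_models(genes: list[GeneModel], bed12_path, annotation_path, np_list_path):
    with open(bed12_path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e.length) for e in g.exons) + ","
            starts = ",".join(str(e.start - g.interval.start) for e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        str(g.interval.start),
                        str(g.interval.end),
                        g.symbol,
                        "0",
                        g.strand,
                        str(g.interval.start),
                        str(g.interval.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
    with open(annotation_path, "w") as fh:
        fh.write("symbol\thi_rank\tpli\n")
        for g in genes:
            hi = "NA" if math.isnan(g.hi_rank) else f"{g.hi_rank:.4f}"
            pli = "NA" if math.isnan(g.pli) else f"{g.pli:.4f}"
            fh.write(f"{g.symbol}\t{hi}\t{pli}\n")
    with open(np_list_path, "w") as fh:
        fh.write("# simulated neuropsychiatric candidate-gene panel\n")
        for g in genes:
            if g.is_np_gene:
                fh.write(g.symbol + "\n")


def write_simulation(params: SimulationParams, out_dir: str | Path) -> dict[str, Path]:
    """Emit a full simulated input bundle plus truth.json into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = simulate_gene_annotation(params)
    cohort, truth = simulate_cohort(params, genes)
    paths = {
        "cohort": out / "cohort.tsv",
        "cnv": out / "cnvs.tsv",
        "genes_bed": out / "genes.bed",
        "gene_annotations": out / "gene_annotations.tsv",
        "np_list": out / "np_genes.txt",
        "truth": out / "truth.json",
    }
    write_cohort(cohort, paths["cohort"], paths["cnv"])
    write_gene_models(genes, paths["genes_bed"], paths["gene_annotations"], paths["np_list"])
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
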