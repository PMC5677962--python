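"""Multiple-hit CNV burden over a neuropsychiatric candidate-gene panel.

Counts, per QC-passing patient, the additional CNVs (i.e. everything
except the defining locus rearrangement) that overlap at least one exon of
a panel gene, and compares that burden between feature-positive and
feature-negative patients with a rank test.  The burden unit is CNVs — a
single CNV hitting three panel genes counts once; a per-gene hit count is
carried as a secondary column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .cohort import (
    CNVCall,
    Cohort,
    GeneModel,
    TriState,
    UndefinedStatisticError,
)

__all__ = [
    "NPHit",
    "BurdenTable",
    "cnv_np_hits",
    "burden_counts",
    "burden_vs_feature",
    "burden_histogram",
]


@dataclass(frozen=True)
class NPHit:
    patient_id: str
    cnv: CNVCall
    genes_hit: tuple[str, ...]


@dataclass(frozen=True)
class BurdenTable:
    """Per-patient burden of panel-gene-hitting additional CNVs.

    counts: DataFrame (patient_id, n_cnvs, n_gene_hits); hits: long-format
    DataFrame with one row per (CNV, gene) pair.
    """

    counts: pd.DataFrame
    hits: pd.DataFrame

    def matrix(self) -> pd.DataFrame:
        """Patients x genes matrix with values '', 'DEL', 'DUP' (or both)."""
        patients = self.counts["patient_id"].tolist()
        genes = sorted(self.hits["gene"].unique()) if len(self.hits) else []
        mat = pd.DataFrame("", index=patients, columns=genes, dtype=object)
        for row in self.hits.itertuples(index=False):
            cur = mat.at[row.patient_id, row.gene]
            types = set(cur.split(";")) - {""} | {row.type}
            mat.at[row.patient_id, row.gene] = ";".join(sorted(types))
        mat.index.name = "patient_id"
        return mat


def cnv_np_hits(cnv: CNVCall, genes: Sequence[GeneModel]) -> list[str]:
    """Panel genes with >= 1 bp of exonic overlap with the CNV, sorted.

    Intronic-only overlap does not count: the overlap must touch an exon.
    """
    hit = set()
    for g in genes:
        if not g.is_np_gene or g.interval.chrom != cnv.interval.chrom:
            continue
        for e in g.exons:
            if e.start < cnv.interval.end and cnv.interval.start < e.end:
                hit.add(g.symbol)
                break
    return sorted(hit)


def _is_locus_cnv(cnv: CNVCall, cohort: Cohort) -> bool:
    return cnv.interval.overlaps(cohort.locus)


def burden_counts(cohort: Cohort, genes: Sequence[GeneModel]) -> BurdenTable:
    """Per-patient counts of distinct additional panel-hitting CNVs.

    Only QC-passing patients are tabulated.  The defining locus
    rearrangement never counts: any CNV overlapping the configured locus
    is excluded (non-locus CNVs elsewhere on the same chromosome still
    count).  Deletions and duplications both count as hits.
    """
    count_rows, hit_rows = [], []
    for p in cohort:
        if not p.array_qc_pass:
            continue
        n_cnvs = 0
        n_gene_hits = 0
        for c in p.cnvs:
            if _is_locus_cnv(c, cohort):
                continue
            symbols = cnv_np_hits(c, genes)
            if not symbols:
                continue
            n_cnvs += 1
            n_gene_hits += len(symbols)
            for s in symbols:
                hit_rows.append(
                    {
                        "patient_id": p.id,
                        "chrom": c.interval.chrom,
                        "start": c.interval.start,
                        "end": c.interval.end,
                        "type": c.dosage_type,
                        "gene": s,
                    }
                )
        count_rows.append(
            {"patient_id": p.id, "n_cnvs": n_cnvs, "n_gene_hits": n_gene_hits}
        )
    counts = pd.DataFrame(count_rows, columns=["patient_id", "n_cnvs", "n_gene_hits"])
    hits = pd.DataFrame(
        hit_rows, columns=["patient_id", "chrom", "start", "end", "type", "gene"]
    )
    return BurdenTable(counts=counts, hits=hits)


def burden_histogram(table: BurdenTable) -> dict[str, int]:
    """Counts of patients with exactly 1, exactly 2 and >= 3 panel CNVs."""
    c = table.counts["n_cnvs"]
    return {
        "1": int((c == 1).sum()),
        "2": int((c == 2).sum()),
        "3+": int((c >= 3).sum()),
        "any": int((c >= 1).sum()),
    }


def burden_vs_feature(
    table: BurdenTable, cohort: Cohort, feature: str
) -> tuple[float, float, dict[str, float]]:
    """Rank comparison of CNV burden between feature groups.

    Two-sided Mann-Whitney U with normal approximation and tie correction
    (no continuity correction, so identical groups give p = 1); returns
    (U statistic, p, group mean counts).  Patients uninformative for the
    feature are dropped; an empty group is an undefined comparison.
    """
    status = {}
    for p in cohort:
        st = p.phenotypes.values.get(feature, TriState.UNKNOWN)
        if st is not TriState.UNKNOWN:
            status[p.id] = st is TriState.PRESENT
    df = table.counts
    mask = df["patient_id"].map(status)
    present = df.loc[mask == True, "n_cnvs"].to_numpy()  # noqa: E712
    absent = df.loc[mask == False, "n_cnvs"].to_numpy()  # noqa: E712
    if present.size == 0 or absent.size == 0:
        raise UndefinedStatisticError(
            f"both feature groups must be non-empty for {feature!r}"
        )
    res = mannwhitneyu(
        present, absent, alternative="two-sided", method="asymptotic",
        use_continuity=False,
    )
    means = {"present": float(np.mean(present)), "absent": float(np.mean(absent))}
    return float(res.statistic), float(res.pvalue), means
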