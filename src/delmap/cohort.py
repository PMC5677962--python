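"""Cohort, CNV and gene-model I/O for deletion-locus phenotype mapping.

Internal genomic coordinates are 0-based half-open (BED convention).  The
cohort-facing CNV table dialect is 1-based inclusive, as clinical tables
conventionally are; conversion happens only at the I/O boundary.

Phenotype features are tri-state (present / absent / unknown).  Unknown
never contributes to the numerator or the denominator of any prevalence.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_LOCUS",
    "TriState",
    "GenomicInterval",
    "CNVCall",
    "PhenotypeProfile",
    "Patient",
    "Cohort",
    "GeneModel",
    "DelmapError",
    "FormatError",
    "CoordinateError",
    "UnknownPatientError",
    "EmptyCohortError",
    "UndefinedStatisticError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "select_mapping_set",
    "summarize_cohort",
    "pooled_center_prevalence",
    "read_center_counts",
    "read_gene_models",
]


# ---------------------------------------------------------------------------
# Errors

class DelmapError(Exception):
    """Base class for all package errors."""


class FormatError(DelmapError):
    """A table or file does not match its documented dialect."""


class CoordinateError(FormatError):
    """An interval is degenerate or inverted."""


class UnknownPatientError(DelmapError):
    """A CNV row references a patient_id absent from the cohort table."""


class EmptyCohortError(DelmapError):
    """A filter produced an empty analysis set."""


class UndefinedStatisticError(DelmapError):
    """A statistic has an empty denominator (e.g. no informative patients)."""


class ValidationError(DelmapError):
    """Inputs violate an operation precondition."""


# ---------------------------------------------------------------------------
# Domain types

class TriState(enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise CoordinateError(
                f"end ({self.end}) must exceed start ({self.start}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


#: The 22q13 mapping domain used throughout: distal chr22 from 42 Mb to the
#: hg19 chromosome end.  Terminal deletion sizes up to ~9.1 Mb from the
#: telomere fall inside it.
DEFAULT_LOCUS = GenomicInterval("chr22", 42_000_000, 51_304_566)

DOSAGE_TYPES = ("DEL", "DUP")
INHERITANCE = ("de_novo", "maternal", "paternal", "unknown")
MECHANISMS = ("simple", "ring", "unbalanced_translocation", "recombined_parental", "unknown")


@dataclass(frozen=True)
class CNVCall:
    """One copy-number event: a DEL or DUP with inheritance and mosaicism."""

    patient_id: str
    interval: GenomicInterval
    dosage_type: str
    inheritance: str = "unknown"
    mosaic: bool = False
    mechanism: str = "unknown"

    def __post_init__(self) -> None:
        if self.dosage_type not in DOSAGE_TYPES:
            raise FormatError(f"bad dosage type {self.dosage_type!r}")
        if self.inheritance not in INHERITANCE:
            raise FormatError(f"bad inheritance {self.inheritance!r}")
        if self.mechanism not in MECHANISMS:
            raise FormatError(f"bad mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class PhenotypeProfile:
    """Mapping feature name -> tri-state status."""

    values: dict[str, TriState] = field(default_factory=dict)

    def status(self, feature: str) -> TriState:
        try:
            return self.values[feature]
        except KeyError:
            raise KeyError(f"unknown feature {feature!r}") from None

    def is_informative(self, feature: str) -> bool:
        return self.status(feature) is not TriState.UNKNOWN

    def is_present(self, feature: str) -> bool:
        return self.status(feature) is TriState.PRESENT

    @property
    def features(self) -> list[str]:
        return list(self.values)


@dataclass(frozen=True)
class Patient:
    id: str
    sex: str  # "M", "F" or "unknown"
    center: str
    array_qc_pass: bool
    phenotypes: PhenotypeProfile
    cnvs: tuple[CNVCall, ...] = ()
    #: proximal breakpoint of the qualifying locus deletion, set by
    #: select_mapping_set; None outside the mapping set
    locus_del_start: int | None = None

    def locus_deletions(self, locus: GenomicInterval) -> list[CNVCall]:
        return [
            c
            for c in self.cnvs
            if c.dosage_type == "DEL" and c.interval.overlaps(locus)
        ]


@dataclass(frozen=True)
class Cohort:
    patients: tuple[Patient, ...]
    locus: GenomicInterval = DEFAULT_LOCUS

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate patient ids: {dup}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for p in self.patients:
            for f in p.phenotypes.features:
                if f not in names:
                    names.append(f)
        return names

    def patient(self, pid: str) -> Patient:
        for p in self.patients:
            if p.id == pid:
                return p
        raise KeyError(pid)


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure plus haploinsufficiency annotations.

    hi_rank is the DECIPHER haploinsufficiency percentile (lower = more
    likely haploinsufficient); pli the ExAC probability of intolerance to
    loss-of-function variation.  Either may be missing (NaN).
    """

    symbol: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]
    hi_rank: float = math.nan
    pli: float = math.nan
    is_np_gene: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r} for {self.symbol}")
        srt = sorted(self.exons, key=lambda e: e.start)
        for e in srt:
            if not self.interval.contains(e):
                raise CoordinateError(f"exon {e} outside gene {self.symbol}")
        for a, b in zip(srt, srt[1:]):
            if a.end > b.start:
                raise CoordinateError(f"overlapping exons in {self.symbol}")


# ---------------------------------------------------------------------------
# Cohort table I/O

_COHORT_MANDATORY = ("patient_id", "sex", "center", "array_qc_pass")
_CNV_MANDATORY = (
    "patient_id",
    "chrom",
    "start_1based",
    "end_1based",
    "type",
    "inheritance",
    "mosaic",
)

_TRI_FROM_CELL = {"1": TriState.PRESENT, "0": TriState.ABSENT, "NA": TriState.UNKNOWN}
_CELL_FROM_TRI = {v: k for k, v in _TRI_FROM_CELL.items()}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table missing mandatory column(s): {', '.join(missing)}")


def read_cohort(
    cohort_table_path: str | Path,
    cnv_table_path: str | Path,
    locus: GenomicInterval = DEFAULT_LOCUS,
) -> Cohort:
    """Load a cohort table and its CNV calls.

    The cohort TSV carries patient_id, sex {M,F,NA}, center, array_qc_pass
    {1,0}, then one column per binary feature with cells {1,0,NA}.  The CNV
    TSV is 1-based inclusive and converted to internal 0-based half-open
    coordinates here.
    """
    cdf = _read_tsv(cohort_table_path)
    _require_columns(cdf, _COHORT_MANDATORY, "cohort")
    feature_cols = [c for c in cdf.columns if c not in _COHORT_MANDATORY]

    vdf = _read_tsv(cnv_table_path)
    _require_columns(vdf, _CNV_MANDATORY, "CNV")

    cnvs_by_patient: dict[str, list[CNVCall]] = {}
    known_ids = set(cdf["patient_id"])
    for i, row in enumerate(vdf.itertuples(index=False), start=2):  # header = line 1
        pid = row.patient_id
        if pid not in known_ids:
            raise UnknownPatientError(
                f"CNV table line {i}: patient_id {pid!r} not in cohort table"
            )
        try:
            start1, end1 = int(row.start_1based), int(row.end_1based)
        except ValueError as exc:
            raise FormatError(f"CNV table line {i}: non-integer coordinate") from exc
        if end1 < start1:
            raise CoordinateError(
                f"CNV table line {i}: end ({end1}) before start ({start1})"
            )
        mech = getattr(row, "mechanism", "unknown") or "unknown"
        call = CNVCall(
            patient_id=pid,
            interval=GenomicInterval(row.chrom, start1 - 1, end1),
            dosage_type=row.type,
            inheritance=row.inheritance,
            mosaic=row.mosaic == "1",
            mechanism=mech,
        )
        cnvs_by_patient.setdefault(pid, []).append(call)

    patients = []
    for d in cdf.to_dict("records"):  # robust to non-identifier feature names
        pheno = {}
        for f in feature_cols:
            cell = d[f]
            if cell not in _TRI_FROM_CELL:
                raise FormatError(
                    f"cohort table: bad cell {cell!r} for feature {f!r}, "
                    f"patient {d['patient_id']!r} (expected 1/0/NA)"
                )
            pheno[f] = _TRI_FROM_CELL[cell]
        sex = d["sex"] if d["sex"] in ("M", "F") else "unknown"
        patients.append(
            Patient(
                id=d["patient_id"],
                sex=sex,
                center=d["center"],
                array_qc_pass=d["array_qc_pass"] == "1",
                phenotypes=PhenotypeProfile(pheno),
                cnvs=tuple(cnvs_by_patient.get(d["patient_id"], ())),
            )
        )
    return Cohort(tuple(patients), locus=locus)


def write_cohort(
    cohort: Cohort,
    cohort_table_path: str | Path,
    cnv_table_path: str | Path,
) -> None:
    """Write a cohort back to the two-table TSV dialect (round-trip safe)."""
    features = cohort.feature_names
    with open(cohort_table_path, "w") as fh:
        fh.write("# cohort table; feature cells: 1=present 0=absent NA=unknown\n")
        fh.write("\t".join(_COHORT_MANDATORY + tuple(features)) + "\n")
        for p in cohort:
            cells = [
                p.id,
                p.sex if p.sex in ("M", "F") else "NA",
                p.center,
                "1" if p.array_qc_pass else "0",
            ]
            for f in features:
                st = p.phenotypes.values.get(f, TriState.UNKNOWN)
                cells.append(_CELL_FROM_TRI[st])
            fh.write("\t".join(cells) + "\n")
    with open(cnv_table_path, "w") as fh:
        fh.write("# CNV table; coordinates 1-based inclusive\n")
        fh.write("\t".join(_CNV_MANDATORY + ("mechanism",)) + "\n")
        for p in cohort:
            for c in p.cnvs:
                fh.write(
                    "\t".join(
                        [
                            p.id,
                            c.interval.chrom,
                            str(c.interval.start + 1),
                            str(c.interval.end),
                            c.dosage_type,
                            c.inheritance,
                            "1" if c.mosaic else "0",
                            c.mechanism,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Analysis-set selection and summaries

def locus_deletion_start(patient: Patient, locus: GenomicInterval) -> int | None:
    """Proximal breakpoint: minimum start among locus-overlapping deletions."""
    dels = patient.locus_deletions(locus)
    if not dels:
        return None
    return min(c.interval.start for c in dels)


def select_mapping_set(cohort: Cohort) -> Cohort:
    """Restrict to QC-passing carriers of a locus deletion.

    Region mapping operates on patients with array data passing QC who carry
    at least one deletion overlapping the locus; duplication-only carriers
    are excluded.  Each retained patient is annotated with the proximal
    breakpoint of its locus deletion (minimum start among qualifying DELs).
    """
    kept = []
    for p in cohort:
        if not p.array_qc_pass:
            continue
        bp = locus_deletion_start(p, cohort.locus)
        if bp is None:
            continue
        kept.append(replace(p, locus_del_start=bp))
    if not kept:
        raise EmptyCohortError("no QC-passing locus-deletion carriers in cohort")
    return Cohort(tuple(kept), locus=cohort.locus)


def summarize_cohort(cohort: Cohort, features: Sequence[str]) -> pd.DataFrame:
    """Per-feature counts: n_present / n_informative, unknowns excluded.

    Returns a DataFrame with columns feature, n_present, n_informative,
    fraction; fraction is NaN when no patient is informative.
    """
    rows = []
    known = set(cohort.feature_names)
    for f in features:
        if f not in known:
            raise KeyError(f"unknown feature {f!r}")
        n_inf = n_pres = 0
        for p in cohort:
            st = p.phenotypes.values.get(f, TriState.UNKNOWN)
            if st is TriState.UNKNOWN:
                continue
            n_inf += 1
            n_pres += st is TriState.PRESENT
        rows.append(
            {
                "feature": f,
                "n_present": n_pres,
                "n_informative": n_inf,
                "fraction": n_pres / n_inf if n_inf else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["feature", "n_present", "n_informative", "fraction"])


def read_center_counts(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ("center", "n_cases", "n_screened"), "center counts")
    df = df.assign(n_cases=df["n_cases"].astype(int), n_screened=df["n_screened"].astype(int))
    return df


def pooled_center_prevalence(center_counts: pd.DataFrame) -> tuple[float, float, float]:
    """Pooled case fraction across screening centers, with per-center range.

    Returns (pooled, per_center_min, per_center_max) as fractions.  Pooling
    is Σcases / Σscreened, i.e. every screened individual weighs equally.
    """
    df = center_counts
    if (df["n_screened"] <= 0).any():
        raise ValidationError("n_screened must be positive for every center")
    if (df["n_cases"] > df["n_screened"]).any():
        bad = df.loc[df["n_cases"] > df["n_screened"], "center"].tolist()
        raise ValidationError(f"n_cases exceeds n_screened for center(s): {bad}")
    per = df["n_cases"] / df["n_screened"]
    pooled = df["n_cases"].sum() / df["n_screened"].sum()
    return float(pooled), float(per.min()), float(per.max())


# ---------------------------------------------------------------------------
# Gene models (BED12 + annotation TSV + plain gene list)

def read_gene_models(
    bed12_path: str | Path,
    annotation_path: str | Path | None = None,
    np_list_path: str | Path | None = None,
) -> list[GeneModel]:
    """Read gene models from BED12, joining HI/pLI and the NP-gene list.

    Exons are reconstructed from the block fields (blockStarts are relative
    to chromStart).  Annotation join is by exact, case-sensitive symbol;
    genes absent from the annotation table get missing HI/pLI and remain
    usable for overlap queries.
    """
    annot: dict[str, tuple[float, float]] = {}
    if annotation_path is not None:
        adf = _read_tsv(annotation_path)
        _require_columns(adf, ("symbol", "hi_rank", "pli"), "gene annotation")
        for row in adf.itertuples(index=False):
            hi = float(row.hi_rank) if row.hi_rank not in ("", "NA") else math.nan
            pli = float(row.pli) if row.pli not in ("", "NA") else math.nan
            annot[row.symbol] = (hi, pli)

    np_genes: set[str] = set()
    if np_list_path is not None:
        with open(np_list_path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    np_genes.add(line)

    genes: list[GeneModel] = []
    with open(bed12_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{bed12_path} line {lineno}: expected 12 BED fields")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",") if x != ""]
            starts = [int(x) for x in parts[11].rstrip(",").split(",") if x != ""]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(
                    f"{bed12_path} line {lineno}: blockCount {n_blocks} does not "
                    f"match {len(sizes)} sizes / {len(starts)} starts"
                )
            exons = tuple(
                GenomicInterval(chrom, start + s, start + s + sz)
                for s, sz in zip(starts, sizes)
            )
            hi, pli = annot.get(name, (math.nan, math.nan))
            genes.append(
                GeneModel(
                    symbol=name,
                    interval=GenomicInterval(chrom, start, end),
                    strand=strand,
                    exons=exons,
                    hi_rank=hi,
                    pli=pli,
                    is_np_gene=name in np_genes,
                )
            )
    return genes
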