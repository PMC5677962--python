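"""Shared fixtures: all test data is built programmatically."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from delmap import (
    CNVCall,
    Cohort,
    DEFAULT_LOCUS,
    GenomicInterval,
    Patient,
    PhenotypeProfile,
    TriState,
)


def make_patient(
    pid: str,
    bp: int | None = None,
    features: dict[str, str] | None = None,
    sex: str = "F",
    qc: bool = True,
    dosage: str = "DEL",
    extra_cnvs: tuple[CNVCall, ...] = (),
    locus: GenomicInterval = DEFAULT_LOCUS,
) -> Patient:
    """A patient with a terminal locus rearrangement starting at bp."""
    tri = {"present": TriState.PRESENT, "absent": TriState.ABSENT,
           "unknown": TriState.UNKNOWN, "1": TriState.PRESENT,
           "0": TriState.ABSENT, "NA": TriState.UNKNOWN}
    cnvs = list(extra_cnvs)
    if bp is not None:
        cnvs.insert(
            0,
            CNVCall(
                patient_id=pid,
                interval=GenomicInterval(locus.chrom, bp, locus.end),
                dosage_type=dosage,
            ),
        )
    return Patient(
        id=pid,
        sex=sex,
        center="T",
        array_qc_pass=qc,
        phenotypes=PhenotypeProfile(
            {k: tri[v] for k, v in (features or {}).items()}
        ),
        cnvs=tuple(cnvs),
    )


def make_cohort(patients, locus: GenomicInterval = DEFAULT_LOCUS) -> Cohort:
    return Cohort(tuple(patients), locus=locus)


@pytest.fixture
def small_mapping_cohort() -> Cohort:
    """8 informative deletion carriers with breakpoints across the locus.

    The five proximal carriers are feature-present, the three distal ones
    absent: a clean enrichment for breakpoints below ~45 Mb.
    """
    bps = [42_300_000, 43_100_000, 43_600_000, 44_200_000, 44_700_000,
           48_500_000, 49_600_000, 50_800_000]
    labels = ["1", "1", "1", "1", "1", "0", "0", "0"]
    return make_cohort(
        make_patient(f"P{i:02d}", bp=bp, features={"speech_absent": lab})
        for i, (bp, lab) in enumerate(zip(bps, labels))
    )
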