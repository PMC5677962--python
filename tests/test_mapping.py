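"""Window profiles, candidate regions, Fisher machinery, permutations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delmap import (
    DEFAULT_LOCUS,
    GenomicInterval,
    MappingParams,
    UndefinedStatisticError,
    ValidationError,
    extract_candidate_region,
    fisher_enrichment,
    fisher_exact_2x2,
    global_prevalence,
    map_feature,
    sampling_pvalue,
    window_profile,
)
from delmap.mapping import haldane_sample_or, candidate_genes
from delmap.cohort import GeneModel

from conftest import make_cohort, make_patient
from oracles import (
    cmle_oracle,
    exact_ci_oracle,
    fisher_p_oracle,
    mapping_or_oracle,
    permutation_p_oracle,
)


class TestGlobalPrevalence:
    @pytest.mark.parametrize(
        "n_present, n_absent, n_unknown, exp_p, exp_se",
        [
            (23, 27, 0, 0.46, math.sqrt(0.46 * 0.54 / 50)),
            (0, 10, 0, 0.0, 0.0),
            (5, 5, 3, 0.5, math.sqrt(0.25 / 10)),
        ],
    )
    def test_closed_form(self, n_present, n_absent, n_unknown, exp_p, exp_se):
        patients = (
            [make_patient(f"A{i}", bp=43_000_000, features={"f": "1"}) for i in range(n_present)]
            + [make_patient(f"B{i}", bp=44_000_000, features={"f": "0"}) for i in range(n_absent)]
            + [make_patient(f"C{i}", bp=45_000_000, features={"f": "NA"}) for i in range(n_unknown)]
        )
        p, se, n = global_prevalence(make_cohort(patients), "f")
        assert p == pytest.approx(exp_p)
        assert se == pytest.approx(exp_se, abs=1e-12)
        assert n == n_present + n_absent

    def test_no_informative_carrier_is_undefined(self):
        cohort = make_cohort([make_patient("A", bp=43_000_000, features={"f": "NA"})])
        with pytest.raises(UndefinedStatisticError):
            global_prevalence(cohort, "f")


class TestWindowProfile:
    def test_interior_breakpoint_in_exactly_30_windows(self):
        bp = 46_000_000
        cohort = make_cohort([make_patient("A", bp=bp, features={"f": "1"})])
        profile = window_profile(cohort, "f", MappingParams(min_informative=1))
        containing = [w for w in profile if w.window.start <= bp < w.window.end]
        assert len(containing) == 30  # 1.5 Mb / 50 kb

    def test_three_present_carriers_prevalence_one_se_zero(self):
        cohort = make_cohort(
            [make_patient(f"A{i}", bp=45_000_000 + i * 1000, features={"f": "1"})
             for i in range(3)]
        )
        profile = window_profile(cohort, "f")
        w = next(w for w in profile if w.n_informative == 3)
        assert w.prevalence == 1.0
        assert w.se == 0.0
        assert not w.masked

    def test_below_min_informative_masked_but_emitted(self):
        cohort = make_cohort(
            [make_patient(f"A{i}", bp=45_000_000, features={"f": "1"}) for i in range(2)]
        )
        profile = window_profile(cohort, "f")
        w = next(w for w in profile if w.n_informative == 2)
        assert w.masked and math.isnan(w.prevalence) and math.isnan(w.se)

    def test_disjoint_tiling_partitions_carriers(self):
        from delmap.simulate import SimulationParams, simulate_cohort
        from delmap import select_mapping_set
        cohort, _ = simulate_cohort(SimulationParams(n_patients=40, rng_seed=9))
        mset = select_mapping_set(cohort)
        params = MappingParams(window_size=1_500_000, step=1_500_000)
        profile = window_profile(mset, "absence_of_speech", params)
        _, _, n = global_prevalence(mset, "absence_of_speech")
        assert sum(w.n_informative for w in profile) == n

    def test_truncated_terminal_window_emitted_at_reduced_width(self):
        cohort = make_cohort([make_patient("A", bp=51_000_000, features={"f": "1"})])
        profile = window_profile(cohort, "f", MappingParams(min_informative=1))
        assert profile[-1].window.end == DEFAULT_LOCUS.end
        assert profile[-1].window.length < 1_500_000
        # the telomeric breakpoint is still mappable: its last containing
        # window is truncated at the locus end
        containing = [w for w in profile
                      if w.window.start <= 51_000_000 < w.window.end]
        assert containing and containing[-1].window.end == DEFAULT_LOCUS.end
        assert all(w.n_informative == 1 for w in containing)


def _stat_profile(anchors_prev, step=50_000, window=1_500_000, chrom="chr22"):
    """Build a WindowStat list from (anchor, prevalence-or-None) pairs."""
    from delmap.mapping import WindowStat
    out = []
    for g, prev in anchors_prev:
        masked = prev is None
        out.append(WindowStat(
            window=GenomicInterval(chrom, g, g + window),
            n_informative=0 if masked else 10,
            n_present=0 if masked else int(prev * 10),
            masked=masked,
            prevalence=math.nan if masked else prev,
            se=math.nan if masked else 0.1,
        ))
    return out


class TestExtractRegion:
    def test_extent_spans_first_to_last_passing_window(self):
        # passing anchors 42.60-44.80 Mb with 1.5 Mb windows -> 42.60-46.30 Mb
        anchors = [(g, 0.9) for g in range(42_600_000, 44_800_001, 50_000)]
        anchors = [(42_550_000, 0.1)] + anchors + [(44_850_000, 0.1)]
        cand = extract_candidate_region(_stat_profile(anchors), 0.46)
        assert cand.region.start == 42_600_000
        assert cand.region.end == 46_300_000

    def test_no_window_above_global_gives_none(self):
        anchors = [(g, 0.2) for g in range(42_000_000, 43_000_000, 50_000)]
        assert extract_candidate_region(_stat_profile(anchors), 0.46) is None

    def test_gap_between_passing_windows_is_spanned(self):
        anchors = [(42_600_000, 0.9), (43_300_000, 0.1), (44_000_000, 0.9)]
        cand = extract_candidate_region(_stat_profile(anchors), 0.46)
        assert cand.region.start == 42_600_000
        assert cand.region.end == 45_500_000
        assert cand.n_windows_passing == 2

    def test_masked_windows_never_pass(self):
        anchors = [(42_600_000, None), (43_000_000, 0.9)]
        cand = extract_candidate_region(_stat_profile(anchors), 0.46)
        assert cand.region.start == 43_000_000

    def test_anchor_mode_spans_anchors_only(self):
        anchors = [(42_600_000, 0.9), (42_650_000, 0.9)]
        cand = extract_candidate_region(
            _stat_profile(anchors), 0.46, region_mode="anchor", step=50_000
        )
        assert cand.region.start == 42_600_000
        assert cand.region.end == 42_700_000


class TestFisher:
    def test_sample_or_closed_form(self):
        fr = fisher_exact_2x2(8, 2, 12, 28)
        assert fr.or_sample == pytest.approx((8 * 28) / (2 * 12))
        assert fr.p == pytest.approx(fisher_p_oracle(8, 2, 12, 28), abs=1e-12)
        assert fr.or_cmle == pytest.approx(cmle_oracle(8, 2, 12, 28), rel=1e-4)

    def test_independence_table(self):
        fr = fisher_exact_2x2(2, 8, 8, 32)
        assert fr.or_sample == pytest.approx(1.0)
        assert fr.p == pytest.approx(1.0)

    def test_zero_cell_haldane_and_infinite_cmle(self):
        fr = fisher_exact_2x2(5, 0, 10, 30)
        assert fr.or_sample == pytest.approx((5.5 * 30.5) / (0.5 * 10.5))
        assert math.isinf(fr.or_cmle)
        assert math.isinf(fr.ci_high)
        lo_oracle, _ = exact_ci_oracle(5, 0, 10, 30)
        assert fr.ci_low == pytest.approx(lo_oracle, rel=1e-4)
        assert 0 < fr.ci_low < math.inf

    def test_degenerate_margin(self):
        fr = fisher_exact_2x2(0, 0, 3, 4)
        assert fr.p == 1.0
        assert math.isnan(fr.or_cmle)

    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 8),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        fr = fisher_exact_2x2(a, b, c, d)
        assert fr.p == pytest.approx(fisher_p_oracle(a, b, c, d), abs=1e-10)
        oracle = cmle_oracle(a, b, c, d)
        if math.isnan(oracle):
            assert math.isnan(fr.or_cmle)
        elif math.isinf(oracle):
            assert math.isinf(fr.or_cmle)
        elif oracle == 0.0:
            assert fr.or_cmle == 0.0
        else:
            assert fr.or_cmle == pytest.approx(oracle, rel=1e-3)
            lo, hi = exact_ci_oracle(a, b, c, d)
            assert fr.ci_low == pytest.approx(lo, rel=1e-3, abs=1e-9)
            if math.isinf(hi):
                assert math.isinf(fr.ci_high)
            else:
                assert fr.ci_high == pytest.approx(hi, rel=1e-3)
            assert fr.ci_low <= fr.or_cmle <= fr.ci_high

    @given(
        a=st.integers(0, 20), b=st.integers(0, 20),
        c=st.integers(0, 20), d=st.integers(0, 20),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_adding_present_carrier_in_region_never_lowers_sample_or(self, a, b, c, d):
        assert haldane_sample_or(a + 1, b, c, d) >= haldane_sample_or(a, b, c, d)


class TestEnrichment:
    def test_counts_and_membership(self, small_mapping_cohort):
        region = GenomicInterval("chr22", 42_000_000, 45_000_000)
        res = fisher_enrichment(small_mapping_cohort, "speech_absent", region)
        assert (res.a, res.b, res.c, res.d) == (5, 0, 0, 3)
        assert res.regional_prevalence == 1.0
        assert res.global_prevalence == pytest.approx(5 / 8)

    def test_span_membership_counts_overlapping_deletions(self, small_mapping_cohort):
        # terminal deletions all reach the locus end, so every carrier
        # overlaps a distal region even when its breakpoint is proximal
        region = GenomicInterval("chr22", 50_000_000, 51_000_000)
        res = fisher_enrichment(
            small_mapping_cohort, "speech_absent", region,
            MappingParams(membership="span"),
        )
        assert res.a + res.b == 8
        res_start = fisher_enrichment(small_mapping_cohort, "speech_absent", region)
        assert res_start.a + res_start.b == 1

    def test_region_outside_locus_rejected(self, small_mapping_cohort):
        with pytest.raises(ValidationError):
            fisher_enrichment(
                small_mapping_cohort, "speech_absent",
                GenomicInterval("chr22", 1_000_000, 2_000_000),
            )


class TestSamplingPvalue:
    def test_all_present_degenerate_p_zero(self):
        cohort = make_cohort(
            [make_patient(f"A{i}", bp=43_000_000 + i * 500_000, features={"f": "1"})
             for i in range(6)]
        )
        p = sampling_pvalue(cohort, "f", observed_or=0.0, params=MappingParams(rng_seed=1))
        assert p == 0.0

    def test_exact_mode_matches_brute_force_oracle(self, small_mapping_cohort):
        cohort = small_mapping_cohort
        res = map_feature(cohort, "speech_absent", MappingParams(rng_seed=0))
        observed = res.association.or_sample
        p_exact = sampling_pvalue(cohort, "speech_absent", observed, exact=True)
        bps = sorted(
            (p.id, min(c.interval.start for c in p.cnvs)) for p in cohort
        )
        labels = [cohort.patient(pid).phenotypes.is_present("speech_absent")
                  for pid, _ in bps]
        p_oracle = permutation_p_oracle(
            [bp for _, bp in bps], labels, observed,
            DEFAULT_LOCUS.start, DEFAULT_LOCUS.end,
        )
        assert p_exact == pytest.approx(p_oracle, abs=1e-12)

    def test_seeded_reproducibility_and_input_order_invariance(self, small_mapping_cohort):
        params = MappingParams(rng_seed=7, n_permutations=300)
        p1 = sampling_pvalue(small_mapping_cohort, "speech_absent", 3.0, params)
        p2 = sampling_pvalue(small_mapping_cohort, "speech_absent", 3.0, params)
        reversed_cohort = make_cohort(
            reversed(small_mapping_cohort.patients), small_mapping_cohort.locus
        )
        p3 = sampling_pvalue(reversed_cohort, "speech_absent", 3.0, params)
        assert p1 == p2 == p3

    def test_engine_identity_permutation_reproduces_scalar_path(self, small_mapping_cohort):
        """The vectorised engine and the scalar pipeline agree on observed labels."""
        import numpy as np
        from delmap.mapping import _carrier_arrays, _permutation_ors
        cohort = small_mapping_cohort
        params = MappingParams()
        _, bp, de, present = _carrier_arrays(cohort, "speech_absent")
        ors = _permutation_ors(bp, de, present[:, None], cohort.locus, params)
        oracle = mapping_or_oracle(
            list(bp), list(present), cohort.locus.start, cohort.locus.end
        )
        res = map_feature(cohort, "speech_absent", params)
        assert ors[0] == pytest.approx(oracle)
        assert res.association.or_sample == pytest.approx(oracle)

    def test_small_sample_correction(self, small_mapping_cohort):
        params = MappingParams(rng_seed=3, n_permutations=100, small_sample_correction=True)
        p = sampling_pvalue(small_mapping_cohort, "speech_absent", 1e9, params)
        assert p == pytest.approx(1 / 101)


class TestMapFeature:
    def test_strong_signal_recovers_enrichment(self, small_mapping_cohort):
        res = map_feature(small_mapping_cohort, "speech_absent",
                          MappingParams(rng_seed=11))
        assert res.candidate is not None
        assert res.candidate.region.start <= 43_100_000
        assert res.association.or_sample > 1.0
        assert res.association.sampling_p is not None

    def test_all_unknown_feature_is_undefined(self):
        cohort = make_cohort(
            [make_patient(f"A{i}", bp=43_000_000 + i, features={"f": "NA"})
             for i in range(3)]
        )
        with pytest.raises(UndefinedStatisticError):
            map_feature(cohort, "f")

    def test_feature_subseed_independent_of_feature_order(self):
        cohort = make_cohort(
            [make_patient(f"A{i}", bp=43_000_000 + i * 700_000,
                          features={"f1": "1" if i % 2 else "0", "f2": "0" if i < 4 else "1"})
             for i in range(8)]
        )
        params = MappingParams(rng_seed=5, n_permutations=200)
        r12 = [map_feature(cohort, f, params).association for f in ("f1", "f2")]
        r21 = [map_feature(cohort, f, params).association for f in ("f2", "f1")]
        for a, b in zip(r12, reversed(r21)):
            if a is None:
                assert b is None
            else:
                assert a.sampling_p == b.sampling_p


class TestCandidateGenes:
    def _genes(self):
        def g(symbol, start, end, hi, pli):
            return GeneModel(
                symbol=symbol,
                interval=GenomicInterval("chr22", start, end),
                strand="+",
                exons=(GenomicInterval("chr22", start, end),),
                hi_rank=hi,
                pli=pli,
            )
        return [
            g("INSIDE", 43_000_000, 43_100_000, 5.0, 0.99),
            g("EDGE", 44_900_000, 45_200_000, 1.0, 0.5),
            g("OUTSIDE", 50_000_000, 50_100_000, 2.0, 0.9),
            g("NOANN", 43_500_000, 43_600_000, math.nan, math.nan),
        ]

    def test_overlap_classes_and_ranking(self):
        region = GenomicInterval("chr22", 42_600_000, 45_000_000)
        df = candidate_genes(region, self._genes())
        assert list(df["symbol"]) == ["EDGE", "INSIDE", "NOANN"]
        assert df.loc[df.symbol == "INSIDE", "overlap_class"].item() == "contained"
        assert df.loc[df.symbol == "EDGE", "overlap_class"].item() == "boundary"
        # missing annotations rank last
        assert list(df["symbol"])[-1] == "NOANN"
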