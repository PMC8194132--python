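"""Decision tree: classification algebra, reflex composition, invalid
handling, cohort split and treatment allocation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alkcea import (
    StrategyName,
    TruthStatus,
    allocate_treatments,
    build_split,
    classification_probabilities,
    no_testing_allocation,
    resolve_invalids,
    strategy_accuracy,
)
from alkcea.synthetic import GeneratorConfig, enumerate_event_tree, generate_parameter_set

fractions = st.floats(min_value=0.0, max_value=1.0)


class TestClassificationProbabilities:
    def test_ihc_values(self):
        tp, fp, tn, fn = classification_probabilities(0.034, 0.968, 0.979)
        assert tp == pytest.approx(0.032912, abs=1e-9)
        assert fp == pytest.approx(0.020286, abs=1e-9)
        assert tn == pytest.approx(0.945714, abs=1e-9)
        assert fn == pytest.approx(0.001088, abs=1e-9)

    def test_fish_values(self):
        tp, fp, _, _ = classification_probabilities(0.034, 0.909, 0.998)
        assert tp == pytest.approx(0.030906, abs=1e-9)
        assert fp == pytest.approx(0.001932, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(p=fractions)
    def test_perfect_test(self, p):
        assert classification_probabilities(p, 1.0, 1.0) == (p, 0.0, 1 - p, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(p=fractions, se=fractions, sp=fractions)
    def test_partition_identities(self, p, se, sp):
        tp, fp, tn, fn = classification_probabilities(p, se, sp)
        assert tp + fp + tn + fn == pytest.approx(1.0, abs=1e-12)
        assert tp + fn == pytest.approx(p, abs=1e-12)
        assert fp + tn == pytest.approx(1 - p, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="sensitivity"):
            classification_probabilities(0.03, 1.2, 0.9)


class TestStrategyAccuracy:
    def test_ngs_is_gold_standard(self, fixture_params):
        ihc = fixture_params.strategy(StrategyName.IHC)
        fish = fixture_params.strategy(StrategyName.FISH)
        se, sp, cost = strategy_accuracy(fixture_params.strategy("NGS"),
                                         ihc, fish, 0.034)
        assert (se, sp, cost) == (1.0, 1.0, 475.0)

    def test_reflex_serial_composition(self, fixture_params):
        ihc = fixture_params.strategy(StrategyName.IHC)
        fish = fixture_params.strategy(StrategyName.FISH)
        se, sp, cost = strategy_accuracy(fixture_params.strategy("REFLEX"),
                                         ihc, fish, 0.034)
        assert se == pytest.approx(0.968 * 0.909, abs=1e-12)
        assert sp == pytest.approx(1 - 0.021 * 0.002, abs=1e-12)
        p_ihc_pos = 0.034 * 0.968 + 0.966 * 0.021
        assert cost == pytest.approx(60.28 + p_ihc_pos * 111.36, abs=1e-9)

    def test_reflex_with_perfect_components(self, fixture_params):
        ihc = fixture_params.strategy(StrategyName.IHC).model_copy(
            update={"sensitivity": 1.0, "specificity": 1.0})
        fish = fixture_params.strategy(StrategyName.FISH).model_copy(
            update={"sensitivity": 1.0, "specificity": 1.0})
        p = 0.05
        se, sp, cost = strategy_accuracy(fixture_params.strategy("REFLEX"),
                                         ihc, fish, p)
        assert (se, sp) == (1.0, 1.0)
        assert cost == pytest.approx(ihc.unit_cost + p * fish.unit_cost)

    @settings(max_examples=50, deadline=None)
    @given(se_i=fractions, sp_i=fractions, se_f=fractions, sp_f=fractions)
    def test_reflex_bounds(self, fixture_params, se_i, sp_i, se_f, sp_f):
        """Serial confirmation can only lose sensitivity and gain specificity."""
        ihc = fixture_params.strategy(StrategyName.IHC).model_copy(
            update={"sensitivity": se_i, "specificity": sp_i})
        fish = fixture_params.strategy(StrategyName.FISH).model_copy(
            update={"sensitivity": se_f, "specificity": sp_f})
        se, sp, _ = strategy_accuracy(fixture_params.strategy("REFLEX"),
                                      ihc, fish, 0.034)
        assert se <= min(se_i, se_f) + 1e-12
        assert sp >= max(sp_i, sp_f) - 1e-12


class TestResolveInvalids:
    def test_untested_fraction(self, fixture_params):
        st_ = fixture_params.strategy(StrategyName.IHC)
        resolved, untested, _ = resolve_invalids(st_, fixture_params.rebiopsy,
                                                 st_.unit_cost)
        assert untested == pytest.approx(0.026 * 0.229, abs=1e-9)
        assert resolved == pytest.approx(1 - 0.0059540, abs=1e-6)

    def test_zero_invalid_rate(self, fixture_params):
        st_ = fixture_params.strategy(StrategyName.IHC).model_copy(
            update={"invalid_rate": 0.0})
        resolved, untested, added = resolve_invalids(
            st_, fixture_params.rebiopsy, st_.unit_cost)
        assert (resolved, untested, added) == (1.0, 0.0, 0.0)

    def test_ngs_added_cost(self, fixture_params):
        st_ = fixture_params.strategy(StrategyName.NGS)
        _, _, added = resolve_invalids(st_, fixture_params.rebiopsy, 475.0)
        assert added == pytest.approx(0.034 * 0.771 * (411.22 + 475), abs=1e-6)


class TestBuildSplit:
    def test_fractions_sum_to_one(self, fixture_params):
        s = build_split(fixture_params)
        total = s.tp + s.fp + s.tn + s.fn + s.untested_chemo
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_ngs_only_is_gold_standard(self, params):
        for st_ in params.strategies:
            st_.share_of_patients = 1.0 if st_.name is StrategyName.NGS else 0.0
        s = build_split(params)
        assert s.fp == 0 and s.fn == 0
        assert s.tp == pytest.approx(0.034 * s.resolved, abs=1e-12)

    def test_matches_event_tree_enumerator_on_fixture(self, fixture_params):
        s = build_split(fixture_params)
        e = enumerate_event_tree(fixture_params)
        for f in ("tp", "fp", "tn", "fn", "untested_chemo",
                  "expected_testing_cost", "expected_biopsy_cost"):
            assert getattr(s, f) == pytest.approx(getattr(e, f), rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("mode", ["parallel", "sequential"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumerator_on_random_sets(self, seed, mode):
        p = generate_parameter_set(GeneratorConfig(seed=seed))
        p.diagnosis_mode = mode
        s, e = build_split(p), enumerate_event_tree(p)
        for f in ("tp", "fp", "tn", "fn", "untested_chemo",
                  "expected_testing_cost", "expected_biopsy_cost"):
            assert getattr(s, f) == pytest.approx(getattr(e, f), rel=1e-12, abs=1e-12)

    def test_tp_monotone_in_any_sensitivity(self, params):
        base_tp = build_split(params).tp
        for name in (StrategyName.IHC, StrategyName.FISH):
            p = params.model_copy(deep=True)
            st_ = p.strategy(name)
            st_.sensitivity = min(1.0, st_.sensitivity + 0.02)
            assert build_split(p).tp >= base_tp

    def test_sequential_mode_cheaper_same_fractions(self, params):
        base = build_split(params)
        params.diagnosis_mode = "sequential"
        seq = build_split(params)
        assert seq.total_expected_cost < base.total_expected_cost
        assert (seq.tp, seq.fp, seq.tn, seq.fn) == (base.tp, base.fp, base.tn, base.fn)


class TestAllocation:
    def test_alk_positive_mix(self, fixture_params):
        from alkcea.decision_tree import DiagnosticSplit
        split = DiagnosticSplit(tp=1.0, fp=0, tn=0, fn=0, untested_chemo=0,
                                expected_testing_cost=0, expected_biopsy_cost=0)
        dist = allocate_treatments(split, fixture_params.biomarkers,
                                   fixture_params.allocation(),
                                   fixture_params.no_testing_mix)
        shares = {e.treatment: e.fraction for e in dist.entries}
        # printed 89.38 / 10.63 renormalised to an exact unit sum
        assert shares["alectinib"] == pytest.approx(0.8938 / 1.0001)
        assert shares["crizotinib_alk"] == pytest.approx(0.1063 / 1.0001)
        assert all(e.truth is TruthStatus.ALK_TP for e in dist.entries)

    def test_tn_with_no_downstream_markers_gets_wt_low_mix(self, params):
        from alkcea.decision_tree import DiagnosticSplit
        b = params.biomarkers
        b.egfr_prevalence = b.ros1_prevalence = b.pdl1_high_prevalence = 0.0
        split = DiagnosticSplit(tp=0, fp=0, tn=1.0, fn=0, untested_chemo=0,
                                expected_testing_cost=0, expected_biopsy_cost=0)
        dist = allocate_treatments(split, b, params.allocation(),
                                   params.no_testing_mix)
        shares = {e.treatment: e.fraction for e in dist.entries}
        assert shares == pytest.approx({"cis_pem": 0.30, "carb_pac_bev": 0.10,
                                        "cis_pem_pembro": 0.60})

    def test_fixture_fractions_sum_to_one(self, fixture_params):
        split = build_split(fixture_params)
        dist = allocate_treatments(split, fixture_params.biomarkers,
                                   fixture_params.allocation(),
                                   fixture_params.no_testing_mix)
        assert dist.total() == pytest.approx(1.0, abs=1e-9)

    def test_useless_test_reduces_to_no_testing_mix(self, params):
        """A test that never calls positives, with no other biomarkers,
        allocates exactly like no testing at all."""
        for st_ in params.strategies:
            if st_.name is not StrategyName.REFLEX:
                st_.sensitivity, st_.specificity = 0.0, 1.0
        b = params.biomarkers
        b.egfr_prevalence = b.ros1_prevalence = b.pdl1_high_prevalence = 0.0
        split = build_split(params)
        dist = allocate_treatments(split, b, params.allocation(),
                                   params.no_testing_mix)

        def by_treatment(d):
            agg = {}
            for e in d.entries:
                agg[e.treatment] = agg.get(e.treatment, 0.0) + e.fraction
            return agg

        nt = by_treatment(no_testing_allocation(params))
        tested = by_treatment(dist)
        assert tested == pytest.approx(nt, abs=1e-12)


class TestNoTestingAllocation:
    def test_default_mix_and_truth_flags(self, fixture_params):
        dist = no_testing_allocation(fixture_params)
        p = fixture_params.biomarkers.alk_prevalence
        shares = {}
        for e in dist.entries:
            shares.setdefault(e.treatment, {})[e.truth] = e.fraction
        assert set(shares) == {"cis_pem", "carb_pac_bev", "cis_pem_pembro"}
        for tr, mix_share in fixture_params.no_testing_mix.items():
            assert shares[tr][TruthStatus.ALK_MISSED] == pytest.approx(mix_share * p)
            assert shares[tr][TruthStatus.NON_ALK] == pytest.approx(mix_share * (1 - p))
        assert dist.total() == pytest.approx(1.0, abs=1e-12)

    def test_single_arm_mix(self, params):
        params.no_testing_mix = {"cis_pem": 1.0}
        dist = no_testing_allocation(params)
        assert {e.treatment for e in dist.entries} == {"cis_pem"}
        assert dist.total() == pytest.approx(1.0)
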