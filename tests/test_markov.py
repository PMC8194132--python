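"""Cohort engine: exponential curves, trace structure, discounting and
the analytic closed-form oracle."""

import math

import numpy as np
import pytest

from alkcea import (
    ExponentialCurve,
    build_trace,
    discounted_outcomes,
    exponential_rate,
    fp_adjusted_profile,
    second_line_oneoff_cost,
)


def _arm(params, name="alectinib", **updates):
    return params.treatments[name].model_copy(update=updates)


class TestExponentialRate:
    @pytest.mark.parametrize("median, expected", [
        (2.0, math.log(2) / 2),
        (18.0, math.log(2) / 18),
    ])
    def test_values(self, median, expected):
        assert exponential_rate(median) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("median", [0.0, -3.0])
    def test_rejects_non_positive(self, median):
        with pytest.raises(ValueError):
            exponential_rate(median)

    @pytest.mark.parametrize("median", [0.5, 6.0, 34.8])
    def test_survival_at_median_is_half(self, median):
        curve = ExponentialCurve(exponential_rate(median))
        assert curve.survival(np.array([median]))[0] == pytest.approx(0.5)


class TestFpAdjustedProfile:
    def test_fixture_adjustment(self, fixture_params):
        prof = fp_adjusted_profile(fixture_params.treatments["alectinib"],
                                   fixture_params.fp_adjustment)
        assert (prof.median_pfs, prof.median_os) == (2.0, 18.0)
        assert prof.pfs_stopping_rule_month == 6.0
        # cost structure is the targeted arm's
        assert prof.monthly_drug_cost_pfs == \
            fixture_params.treatments["alectinib"].monthly_drug_cost_pfs

    def test_no_stopping_rule_variant(self, fixture_params):
        adj = fixture_params.fp_adjustment.model_copy(
            update={"stopping_rule_month": None})
        prof = fp_adjusted_profile(fixture_params.treatments["alectinib"], adj)
        assert prof.pfs_stopping_rule_month is None

    def test_identity_adjustment(self, fixture_params):
        base = fixture_params.treatments["alectinib"]
        adj = fixture_params.fp_adjustment.model_copy(update={
            "median_pfs_fp": base.median_pfs, "median_os_fp": base.median_os,
            "stopping_rule_month": None})
        assert fp_adjusted_profile(base, adj).model_dump() == base.model_dump()


class TestBuildTrace:
    def test_occupancy_partition(self, fixture_params):
        for name in fixture_params.treatments:
            tr = build_trace(fixture_params.treatments[name],
                             fixture_params.economics)
            np.testing.assert_allclose(tr.pfs + tr.pd + tr.death, 1.0,
                                       atol=1e-12)
            assert np.all(np.diff(tr.death) >= -1e-15)
            assert np.all(np.diff(tr.pfs) <= 1e-15)
            assert np.all(tr.pd >= -1e-15)

    def test_stopping_rule_empties_pfs(self, fixture_params):
        prof = fp_adjusted_profile(fixture_params.treatments["alectinib"],
                                   fixture_params.fp_adjustment)
        tr = build_trace(prof, fixture_params.economics)
        assert np.all(tr.pfs[6:] == 0.0)
        assert tr.pfs[5] > 0

    def test_equal_curves_have_no_pd(self, fixture_params):
        prof = _arm(fixture_params, median_pfs=18.0, median_os=18.0,
                    pfs_stopping_rule_month=None)
        tr = build_trace(prof, fixture_params.economics)
        np.testing.assert_allclose(tr.pd, 0.0, atol=1e-12)
        np.testing.assert_allclose(tr.entering_pd, 0.0, atol=1e-12)

    def test_entering_pd_totals_progressors(self, fixture_params):
        """With progression strictly faster than death, cumulative entrants
        equal the PFS curve's total loss."""
        prof = _arm(fixture_params, pfs_stopping_rule_month=None)
        tr = build_trace(prof, fixture_params.economics)
        assert tr.entering_pd.sum() == pytest.approx(1.0 - tr.pfs[-1], abs=1e-12)

    def test_inconsistent_inputs_clamped(self, fixture_params):
        prof = _arm(fixture_params, median_pfs=30.0, median_os=10.0,
                    pfs_stopping_rule_month=None)
        tr = build_trace(prof, fixture_params.economics)
        assert np.all(tr.pd >= -1e-15)


class TestDiscountedOutcomes:
    def test_matches_closed_form_without_discounting(self, fixture_params):
        prof = _arm(fixture_params, median_pfs=18.0, median_os=18.0,
                    pfs_stopping_rule_month=None)
        eco = fixture_params.economics.model_copy(update={
            "discount_rate_costs": 0.0, "discount_rate_effects": 0.0})
        av = discounted_outcomes(build_trace(prof, eco),
                                 fixture_params.utilities, prof, None, eco,
                                 include_second_line_cost=False)
        lam, t = math.log(2) / 18, 240.0
        closed_months = (1 - math.exp(-lam * t)) / lam  # = 25.966 months
        assert av.ly * 12 == pytest.approx(closed_months, rel=0.005)

    def test_matches_closed_form_with_discounting(self, fixture_params):
        prof = _arm(fixture_params, median_pfs=18.0, median_os=18.0,
                    pfs_stopping_rule_month=None)
        av = discounted_outcomes(build_trace(prof, fixture_params.economics),
                                 fixture_params.utilities, prof, None,
                                 fixture_params.economics,
                                 include_second_line_cost=False)
        lam, t = math.log(2) / 18, 240.0
        rho = math.log(1.03) / 12
        closed_months = (1 - math.exp(-(lam + rho) * t)) / (lam + rho)
        assert av.ly * 12 == pytest.approx(closed_months, rel=0.005)

    def test_unit_utilities_make_qaly_equal_ly(self, fixture_params):
        u = fixture_params.utilities.model_copy(update={
            "u_pfs": 1.0, "u_pd_active": 1.0, "u_pd_bsc": 1.0})
        prof = fixture_params.treatments["cis_pem"]
        sl = fixture_params.second_line[prof.second_line_link]
        av = discounted_outcomes(build_trace(prof, fixture_params.economics),
                                 u, prof, sl, fixture_params.economics)
        assert av.qaly == pytest.approx(av.ly, rel=1e-12)

    def test_discounted_never_exceeds_undiscounted(self, fixture_params):
        for name, prof in fixture_params.treatments.items():
            sl = fixture_params.second_line[prof.second_line_link]
            av = discounted_outcomes(build_trace(prof, fixture_params.economics),
                                     fixture_params.utilities, prof, sl,
                                     fixture_params.economics)
            assert av.ly <= av.ly_undiscounted
            assert av.qaly <= av.qaly_undiscounted
            assert av.cost <= av.cost_undiscounted
            assert av.qaly <= av.ly

    def test_zero_discount_equalises(self, fixture_params):
        eco = fixture_params.economics.model_copy(update={
            "discount_rate_costs": 0.0, "discount_rate_effects": 0.0})
        prof = fixture_params.treatments["osimertinib"]
        sl = fixture_params.second_line[prof.second_line_link]
        av = discounted_outcomes(build_trace(prof, eco),
                                 fixture_params.utilities, prof, sl, eco)
        assert av.ly == pytest.approx(av.ly_undiscounted, rel=1e-12)
        assert av.cost == pytest.approx(av.cost_undiscounted, rel=1e-12)

    def test_ly_monotone_in_os_and_qaly_in_utility(self, fixture_params):
        eco = fixture_params.economics
        prof_lo = _arm(fixture_params, median_os=40.0)
        prof_hi = _arm(fixture_params, median_os=60.0)
        u = fixture_params.utilities
        av_lo = discounted_outcomes(build_trace(prof_lo, eco), u, prof_lo,
                                    None, eco, include_second_line_cost=False)
        av_hi = discounted_outcomes(build_trace(prof_hi, eco), u, prof_hi,
                                    None, eco, include_second_line_cost=False)
        assert av_hi.ly > av_lo.ly
        u_hi = u.model_copy(update={"u_pfs": min(1.0, u.u_pfs + 0.05)})
        av_u = discounted_outcomes(build_trace(prof_lo, eco), u_hi, prof_lo,
                                   None, eco, include_second_line_cost=False)
        assert av_u.qaly > av_lo.qaly


class TestSecondLineOneOff:
    def test_no_active_treatment_costs_nothing(self, fixture_params):
        sl = fixture_params.second_line["post_chemo"].model_copy(
            update={"share_active_treatment": 0.0})
        assert second_line_oneoff_cost(sl) == 0.0

    def test_exponential_mean_duration(self, fixture_params):
        sl = fixture_params.second_line["post_chemo"].model_copy(update={
            "share_active_treatment": 1.0, "median_pfs_2l": 6.0,
            "monthly_drug_cost": 1000.0, "admin_unit_cost": 0.0})
        assert second_line_oneoff_cost(sl) == pytest.approx(8656.17, abs=0.01)

    def test_linear_in_active_share(self, fixture_params):
        sl = fixture_params.second_line["post_chemo"]
        half = sl.model_copy(update={
            "share_active_treatment": sl.share_active_treatment / 2})
        assert second_line_oneoff_cost(sl) == pytest.approx(
            2 * second_line_oneoff_cost(half), rel=1e-12)
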