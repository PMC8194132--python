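"""Partitioned-survival cohort engine (3 states, monthly cycles).

Per-arm PFS and OS are exponential curves built from medians
(rate = ln 2 / median).  State occupancy is read off the curves
("area under the curve" structure): PFS(t) = min(S_pfs(t), S_os(t)),
Death(t) = 1 - S_os(t), PD(t) = the remainder.  Life-years, QALYs and
costs are accumulated by trapezoidal integration of the discounted
occupancy, which converges to the continuous-time integral; the closed
form for an exponential arm without stopping rule,
(1 - exp(-(lam + rho) T)) / (lam + rho), is the analytic oracle used in
the tests.

Dependence between progression and death is comonotone (one latent
uniform drives both marginals), which is exactly the coupling whose joint
survivor function is the pointwise minimum used above; the
individual-patient microsimulation in :mod:`alkcea.synthetic` draws from
that same coupling, making the two engines estimators of the same
quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import (
    EconomicSettings,
    FalsePositiveAdjustment,
    SecondLineProfile,
    TreatmentProfile,
    UtilitySet,
)

__all__ = [
    "ExponentialCurve",
    "CohortTrace",
    "ArmValue",
    "exponential_rate",
    "fp_adjusted_profile",
    "second_line_oneoff_cost",
    "scaled_monthly_drug_cost",
    "build_trace",
    "discounted_outcomes",
]

_RATE_TIE_TOL = 1e-12


def exponential_rate(median: float) -> float:
    """Monthly event rate lambda = ln 2 / median (median in months)."""
    if median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    return math.log(2.0) / median


@dataclass(frozen=True)
class ExponentialCurve:
    """Exponential survivor function, optionally truncated by a stopping
    rule (all remaining patients experience the event at that month)."""

    rate: float
    stopping_rule_month: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    def survival(self, t: np.ndarray) -> np.ndarray:
        s = np.exp(-self.rate * np.asarray(t, dtype=float))
        if self.stopping_rule_month is not None:
            s = np.where(np.asarray(t, float) >= self.stopping_rule_month, 0.0, s)
        return s


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy; ``times`` are cycle boundaries in months.

    ``entering_pd[t]`` is the fraction of the cohort progressing (leaving
    PFS alive) during cycle t, the basis for the second-line one-off cost.
    """

    times: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    death: np.ndarray
    entering_pd: np.ndarray


def fp_adjusted_profile(base: TreatmentProfile,
                        adj: FalsePositiveAdjustment) -> TreatmentProfile:
    """ALK-targeted arm as experienced by a false positive.

    Keeps the targeted therapy's cost structure but overrides survival:
    rapid progression (short PFS median with an optional stopping rule by
    which everyone has progressed) and an assumed OS median reflecting
    subsequent non-targeted management.
    """
    return base.model_copy(update={
        "median_pfs": adj.median_pfs_fp,
        "median_os": adj.median_os_fp,
        "pfs_stopping_rule_month": adj.stopping_rule_month,
    })


def second_line_oneoff_cost(sl: SecondLineProfile) -> float:
    """Expected one-off second-line cost per progressing patient.

    share on active treatment x monthly (drug + administration) cost x
    expected duration, with duration the exponential mean median / ln 2.
    """
    monthly = sl.monthly_drug_cost + sl.admin_unit_cost
    duration = sl.median_pfs_2l / math.log(2.0)
    return sl.share_active_treatment * monthly * duration


def scaled_monthly_drug_cost(profile: TreatmentProfile,
                             settings: EconomicSettings) -> float:
    """Monthly acquisition cost at the cohort's body size.

    The BSA- and weight-scaled fractions of the cost move linearly with
    body surface area and weight relative to the reference patient; the
    remainder is flat-dosed.
    """
    f_bsa = profile.bsa_scaled_fraction
    f_wt = profile.weight_scaled_fraction
    scale = (1.0 - f_bsa - f_wt
             + f_bsa * settings.body_surface_area / settings.reference_bsa
             + f_wt * settings.body_weight / settings.reference_weight)
    return profile.monthly_drug_cost_pfs * scale


def _n_cycles(settings: EconomicSettings) -> int:
    return int(round(settings.horizon_years * 12.0 / settings.cycle_length_months))


def build_trace(profile: TreatmentProfile, settings: EconomicSettings) -> CohortTrace:
    """Run the partitioned-survival occupancy over the model horizon.

    The PFS rate is clamped to at least the OS rate so PD occupancy stays
    non-negative even for inconsistent user inputs.
    """
    lam_os = exponential_rate(profile.median_os)
    lam_pfs = max(exponential_rate(profile.median_pfs), lam_os)
    pfs_curve = ExponentialCurve(lam_pfs, profile.pfs_stopping_rule_month)
    os_curve = ExponentialCurve(lam_os)

    n = _n_cycles(settings)
    times = np.arange(n + 1, dtype=float) * settings.cycle_length_months
    s_os = os_curve.survival(times)
    s_pfs = np.minimum(pfs_curve.survival(times), s_os)

    pfs = s_pfs
    death = 1.0 - s_os
    pd = 1.0 - pfs - death

    entering = np.zeros(n + 1)
    if lam_pfs - lam_os > _RATE_TIE_TOL or profile.pfs_stopping_rule_month is not None:
        if lam_pfs - lam_os > _RATE_TIE_TOL:
            # progression strictly precedes death under the comonotone
            # coupling, so every PFS exit is a progression
            entering[1:] = pfs[:-1] - pfs[1:]
        else:
            # equal rates: smooth PFS exits are deaths; only the stopping
            # rule forces the survivors to progress
            d_death = np.diff(death)
            entering[1:] = np.maximum(0.0, (pfs[:-1] - pfs[1:]) - d_death)
    return CohortTrace(times=times, pfs=pfs, pd=pd, death=death,
                       entering_pd=entering)


@dataclass(frozen=True)
class ArmValue:
    """Discounted and undiscounted per-patient outcomes for one arm."""

    ly: float
    qaly: float
    cost_drug: float
    cost_admin: float
    cost_second_line: float
    ly_undiscounted: float
    qaly_undiscounted: float
    cost_undiscounted: float

    @property
    def cost(self) -> float:
        return self.cost_drug + self.cost_admin + self.cost_second_line


def _trapz_discounted(values: np.ndarray, times: np.ndarray,
                      monthly_log_rate: float) -> float:
    disc = np.exp(-monthly_log_rate * times)
    return float(np.trapezoid(values * disc, times))


def discounted_outcomes(trace: CohortTrace, utilities: UtilitySet,
                        profile: TreatmentProfile,
                        second_line: Optional[SecondLineProfile],
                        settings: EconomicSettings,
                        include_second_line_cost: bool = True) -> ArmValue:
    """Accumulate discounted LY, QALY and costs over a cohort trace.

    Annual discount rates are converted to continuous monthly rates
    (rho = ln(1 + r) / 12) so the per-cycle factor equals (1 + r)^(-t/12)
    at every cycle boundary.  Drug and administration costs accrue on PFS
    occupancy; the second-line one-off cost is charged to each cycle's
    progressing fraction at the cycle midpoint.  PD utility is blended by
    the linked second line's active-treatment share.
    """
    rho_eff = math.log1p(settings.discount_rate_effects) / 12.0
    rho_cost = math.log1p(settings.discount_rate_costs) / 12.0
    t = trace.times
    alive = trace.pfs + trace.pd

    if second_line is not None:
        share_active = second_line.share_active_treatment
    else:
        share_active = 0.0
    u_pd = (share_active * utilities.u_pd_active
            + (1.0 - share_active) * utilities.u_pd_bsc)
    q_occ = utilities.u_pfs * trace.pfs + u_pd * trace.pd

    ly = _trapz_discounted(alive, t, rho_eff) / 12.0
    qaly = _trapz_discounted(q_occ, t, rho_eff) / 12.0
    ly_undisc = float(np.trapezoid(alive, t)) / 12.0
    qaly_undisc = float(np.trapezoid(q_occ, t)) / 12.0

    cycle = settings.cycle_length_months
    drug_monthly = scaled_monthly_drug_cost(profile, settings)
    admin_monthly = (profile.iv_administrations_per_cycle
                     * profile.admin_unit_cost / cycle)
    cost_drug = drug_monthly * _trapz_discounted(trace.pfs, t, rho_cost)
    cost_admin = admin_monthly * _trapz_discounted(trace.pfs, t, rho_cost)
    drug_undisc = drug_monthly * float(np.trapezoid(trace.pfs, t))
    admin_undisc = admin_monthly * float(np.trapezoid(trace.pfs, t))

    cost_sl = sl_undisc = 0.0
    if include_second_line_cost and second_line is not None:
        oneoff = second_line_oneoff_cost(second_line)
        mid = np.maximum(t - cycle / 2.0, 0.0)
        disc_mid = np.exp(-rho_cost * mid)
        cost_sl = oneoff * float(np.sum(trace.entering_pd * disc_mid))
        sl_undisc = oneoff * float(np.sum(trace.entering_pd))

    return ArmValue(
        ly=ly, qaly=qaly,
        cost_drug=cost_drug, cost_admin=cost_admin, cost_second_line=cost_sl,
        ly_undiscounted=ly_undisc, qaly_undiscounted=qaly_undisc,
        cost_undiscounted=drug_undisc + admin_undisc + sl_undisc)
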