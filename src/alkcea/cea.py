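"""Scenario evaluation and incremental cost-effectiveness comparison.

A scenario is a population size, a distribution over treatment arms and a
per-patient testing cost; its value is the linear aggregation of per-arm
discounted outcomes.  Testing vs no-testing is compared through the
incremental cost-effectiveness ratio per life-year (ICER) and per QALY
(ICUR).  Ratios are kept unrounded internally; nearest-euro rounding is a
reporting-layer concern.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .cascade import compute_cascade
from .decision_tree import (
    ArmDistribution,
    TruthStatus,
    build_split,
    allocate_treatments,
    no_testing_allocation,
)
from .markov import ArmValue, build_trace, discounted_outcomes, fp_adjusted_profile
from .params import ModelParameters

__all__ = ["ScenarioResult", "Dominance", "CEAResult", "arm_value",
           "evaluate_arms", "evaluate_scenario", "compare", "run_base_case",
           "round_euro"]


def round_euro(x: float) -> int:
    """Nearest-euro rounding, half away from zero (as printed tables do)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScenarioResult:
    label: str
    population: float
    testing_cost: float
    treatment_cost: float
    ly: float
    qaly: float
    ly_undiscounted: float = 0.0
    qaly_undiscounted: float = 0.0

    @property
    def total_cost(self) -> float:
        return self.testing_cost + self.treatment_cost


class Dominance(str, enum.Enum):
    NONE = "none"                  # both increments share a sign: ratio valid
    DOMINANT = "dominant"          # cheaper and more effective
    DOMINATED = "dominated"        # dearer and less effective
    UNDEFINED = "undefined"        # zero effect increment


@dataclass(frozen=True)
class CEAResult:
    tested: ScenarioResult
    untested: ScenarioResult
    d_cost: float
    d_ly: float
    d_qaly: float
    icer_per_ly: Optional[float]
    icur_per_qaly: Optional[float]
    dominance_ly: Dominance
    dominance_qaly: Dominance

    @property
    def icer_per_ly_rounded(self) -> Optional[int]:
        return None if self.icer_per_ly is None else round_euro(self.icer_per_ly)

    @property
    def icur_per_qaly_rounded(self) -> Optional[int]:
        return None if self.icur_per_qaly is None else round_euro(self.icur_per_qaly)


def arm_value(params: ModelParameters, treatment: str,
              truth: TruthStatus) -> ArmValue:
    """Discounted per-patient value of one treatment arm for one truth status.

    False positives run the targeted arm's cost structure on the
    FP-adjusted survival curves; every other status uses the arm's own
    curves (missed ALK patients get non-targeted effectiveness unmodified).
    """
    profile = params.treatments[treatment]
    if truth is TruthStatus.ALK_FP:
        profile = fp_adjusted_profile(profile, params.fp_adjustment)
    sl = (params.second_line.get(profile.second_line_link)
          if profile.second_line_link else None)
    trace = build_trace(profile, params.economics)
    return discounted_outcomes(
        trace, params.utilities, profile, sl, params.economics,
        include_second_line_cost=params.include_second_line)


def evaluate_arms(params: ModelParameters,
                  dist: ArmDistribution) -> dict[tuple[str, bool], ArmValue]:
    """Per-arm values keyed by (treatment, is_false_positive), cached per call."""
    cache: dict[tuple[str, bool], ArmValue] = {}
    for e in dist.entries:
        key = (e.treatment, e.truth is TruthStatus.ALK_FP)
        if key not in cache:
            cache[key] = arm_value(params, e.treatment, e.truth)
    return cache


def evaluate_scenario(params: ModelParameters, dist: ArmDistribution,
                      testing_cost_per_patient: float, population: float,
                      label: str) -> ScenarioResult:
    """Aggregate per-arm values over the arm distribution and population."""
    cache = evaluate_arms(params, dist)
    cost = ly = qaly = ly_u = qaly_u = 0.0
    for e in dist.entries:
        av = cache[(e.treatment, e.truth is TruthStatus.ALK_FP)]
        cost += e.fraction * av.cost
        ly += e.fraction * av.ly
        qaly += e.fraction * av.qaly
        ly_u += e.fraction * av.ly_undiscounted
        qaly_u += e.fraction * av.qaly_undiscounted
    return ScenarioResult(
        label=label, population=population,
        testing_cost=population * testing_cost_per_patient,
        treatment_cost=population * cost,
        ly=population * ly, qaly=population * qaly,
        ly_undiscounted=population * ly_u,
        qaly_undiscounted=population * qaly_u)


def _ratio(d_cost: float, d_eff: float) -> tuple[Optional[float], Dominance]:
    if d_eff == 0:
        return None, Dominance.UNDEFINED
    if d_eff > 0 and d_cost < 0:
        return None, Dominance.DOMINANT
    if d_eff < 0 and d_cost > 0:
        return None, Dominance.DOMINATED
    if d_eff < 0 and d_cost < 0:
        # south-west quadrant: ratio is reported on the savings-per-loss scale
        return d_cost / d_eff, Dominance.NONE
    return d_cost / d_eff, Dominance.NONE


def compare(tested: ScenarioResult, untested: ScenarioResult) -> CEAResult:
    """Incremental comparison of the testing scenario against no testing."""
    d_cost = tested.total_cost - untested.total_cost
    d_ly = tested.ly - untested.ly
    d_qaly = tested.qaly - untested.qaly
    icer, dom_ly = _ratio(d_cost, d_ly)
    icur, dom_q = _ratio(d_cost, d_qaly)
    return CEAResult(tested=tested, untested=untested,
                     d_cost=d_cost, d_ly=d_ly, d_qaly=d_qaly,
                     icer_per_ly=icer, icur_per_qaly=icur,
                     dominance_ly=dom_ly, dominance_qaly=dom_q)


def run_base_case(params: ModelParameters,
                  population: Optional[float] = None) -> CEAResult:
    """Full pipeline: cascade -> split -> allocation -> Markov -> comparison.

    ``population`` overrides the cascade's tested count (used by population
    scenarios); both compared scenarios always share the same basis.
    """
    if population is None:
        population = compute_cascade(params.epidemiology).tested
    split = build_split(params)
    dist = allocate_treatments(split, params.biomarkers, params.allocation(),
                               params.no_testing_mix)
    tested = evaluate_scenario(params, dist, split.total_expected_cost,
                               population, "testing")
    nt_dist = no_testing_allocation(params)
    untested = evaluate_scenario(params, nt_dist, 0.0, population, "no-testing")
    return compare(tested, untested)
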