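"""Deterministic and probabilistic sensitivity analyses.

Covers the shipped scenario registry (time horizon, alternative treatment
allocation, false-positive response variants, invalid-rate variants,
sequential diagnosis, no second line, population subsets, a multi-year
testing-rate ramp), one-way tornado analysis, the bivariate
sensitivity/specificity grid for IHC and FISH, and a second-order
Monte-Carlo PSA (beta for utilities, normal for body size / medians /
positivity / invalid rates / rebiopsy probability, gamma for unit costs).

Every analysis works on deep copies: the base parameter set is never
mutated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .cascade import compute_cascade
from .cea import CEAResult, ScenarioResult, compare, run_base_case
from .params import ModelParameters, StrategyName
from .fixture import paper_fixture  # noqa: F401  (registry docs reference it)

__all__ = ["ScenarioSpec", "TornadoEntry", "PSAResult", "get_by_path",
           "set_by_path", "apply_overrides", "run_scenario", "run_scenarios",
           "paper_scenario_registry", "one_way", "default_tornado_variables",
           "bivariate_grid", "run_psa"]


# ---------------------------------------------------------------------------
# dotted-path parameter access


def _resolve(obj: Any, seg: str) -> Any:
    if isinstance(obj, dict):
        return obj[seg]
    if isinstance(obj, list):  # strategies list addressed by name
        for item in obj:
            if getattr(item, "name", None) == StrategyName(seg):
                return item
        raise KeyError(seg)
    return getattr(obj, seg)


def get_by_path(params: ModelParameters, path: str) -> Any:
    obj: Any = params
    for seg in path.split("."):
        obj = _resolve(obj, seg)
    return obj


def set_by_path(params: ModelParameters, path: str, value: Any) -> None:
    segs = path.split(".")
    obj: Any = params
    for seg in segs[:-1]:
        obj = _resolve(obj, seg)
    leaf = segs[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise KeyError(f"unknown parameter path {path!r}")
        obj[leaf] = value
    else:
        if not isinstance(obj, BaseModel) or leaf not in type(obj).model_fields:
            raise KeyError(f"unknown parameter path {path!r}")
        object.__setattr__(obj, leaf, value)


# ---------------------------------------------------------------------------
# scenario analysis


@dataclass(frozen=True)
class ScenarioSpec:
    """One deterministic scenario: overrides applied to a copy of the base.

    ``overrides`` maps dotted parameter paths to values; the remaining
    fields cover structural switches that are not a single numeric leaf.
    ``testing_rate_schedule`` runs one incident cohort per year, each over
    the full horizon at its year's testing rate, and sums the results.
    """

    label: str
    overrides: dict[str, Any] = field(default_factory=dict)
    allocation_variant: Optional[str] = None
    diagnosis_mode: Optional[str] = None
    include_second_line: Optional[bool] = None
    population_subset_share: Optional[float] = None
    testing_rate_schedule: Optional[tuple[float, ...]] = None


def apply_overrides(params: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    p = params.model_copy(deep=True)
    for path, value in spec.overrides.items():
        set_by_path(p, path, value)
    if spec.allocation_variant is not None:
        p.allocation_variant = spec.allocation_variant
    if spec.diagnosis_mode is not None:
        p.diagnosis_mode = spec.diagnosis_mode
    if spec.include_second_line is not None:
        p.include_second_line = spec.include_second_line
    return p


def _sum_results(label: str, parts: Sequence[CEAResult]) -> CEAResult:
    def agg(pick) -> ScenarioResult:
        rs = [pick(r) for r in parts]
        return ScenarioResult(
            label=f"{label}:{rs[0].label}",
            population=sum(r.population for r in rs),
            testing_cost=sum(r.testing_cost for r in rs),
            treatment_cost=sum(r.treatment_cost for r in rs),
            ly=sum(r.ly for r in rs), qaly=sum(r.qaly for r in rs),
            ly_undiscounted=sum(r.ly_undiscounted for r in rs),
            qaly_undiscounted=sum(r.qaly_undiscounted for r in rs))
    return compare(agg(lambda r: r.tested), agg(lambda r: r.untested))


def run_scenario(params: ModelParameters, spec: ScenarioSpec) -> CEAResult:
    """Evaluate one scenario as an independent deterministic run."""
    p = apply_overrides(params, spec)
    if spec.testing_rate_schedule:
        parts = []
        for rate in spec.testing_rate_schedule:
            py = p.model_copy(deep=True)
            py.epidemiology.testing_rate = rate
            parts.append(run_base_case(py))
        return _sum_results(spec.label, parts)
    population = None
    if spec.population_subset_share is not None:
        population = (compute_cascade(p.epidemiology).tested
                      * spec.population_subset_share)
    return run_base_case(p, population=population)


def run_scenarios(params: ModelParameters,
                  specs: Sequence[ScenarioSpec]) -> pd.DataFrame:
    """Run every scenario and tabulate totals, increments and ratios."""
    rows = []
    for spec in specs:
        r = run_scenario(params, spec)
        rows.append({
            "scenario": spec.label,
            "total_cost_tested": r.tested.total_cost,
            "total_cost_untested": r.untested.total_cost,
            "testing_cost": r.tested.testing_cost,
            "d_cost": r.d_cost, "d_ly": r.d_ly, "d_qaly": r.d_qaly,
            "icer_per_ly": r.icer_per_ly, "icur_per_qaly": r.icur_per_qaly,
        })
    return pd.DataFrame(rows).set_index("scenario")


def paper_scenario_registry(params: ModelParameters) -> list[ScenarioSpec]:
    """The shipped deterministic scenario list.

    The adenocarcinoma-only subset share is the non-squamous fraction of
    the candidate population, computed from the epidemiology inputs.
    """
    cas = compute_cascade(params.epidemiology)
    adeno_share = cas.nonsquamous / cas.candidates
    base_rate = params.epidemiology.testing_rate
    return [
        ScenarioSpec("base_case"),
        ScenarioSpec("horizon_10y", {"economics.horizon_years": 10.0}),
        ScenarioSpec("horizon_5y", {"economics.horizon_years": 5.0}),
        ScenarioSpec("horizon_3y", {"economics.horizon_years": 3.0}),
        ScenarioSpec("adenocarcinoma_only",
                     population_subset_share=adeno_share),
        ScenarioSpec("testing_rate_ramp",
                     testing_rate_schedule=(base_rate, 0.85, 0.90)),
        ScenarioSpec("sequential_diagnosis", diagnosis_mode="sequential"),
        ScenarioSpec("invalid_1pct_ihc_fish", {
            "strategies.IHC.invalid_rate": 0.01,
            "strategies.FISH.invalid_rate": 0.01,
            "strategies.REFLEX.invalid_rate": 0.01}),
        ScenarioSpec("invalid_0_all", {
            "strategies.IHC.invalid_rate": 0.0,
            "strategies.FISH.invalid_rate": 0.0,
            "strategies.REFLEX.invalid_rate": 0.0,
            "strategies.NGS.invalid_rate": 0.0}),
        ScenarioSpec("allocation_alternative",
                     allocation_variant="alternative"),
        ScenarioSpec("fp_pfs_1.5", {"fp_adjustment.median_pfs_fp": 1.5}),
        ScenarioSpec("fp_pfs_3", {"fp_adjustment.median_pfs_fp": 3.0}),
        ScenarioSpec("fp_os_15", {"fp_adjustment.median_os_fp": 15.0}),
        ScenarioSpec("fp_os_21", {"fp_adjustment.median_os_fp": 21.0}),
        ScenarioSpec("fp_no_stopping_rule",
                     {"fp_adjustment.stopping_rule_month": None}),
        ScenarioSpec("no_second_line", include_second_line=False),
    ]


# ---------------------------------------------------------------------------
# one-way (tornado) analysis


@dataclass(frozen=True)
class TornadoEntry:
    variable: str
    low_multiplier: float
    high_multiplier: float
    icur_low: Optional[float]
    icur_high: Optional[float]
    span: float


def default_tornado_variables(params: ModelParameters) -> list[tuple[str, float]]:
    """(parameter path, relative delta) pairs, default +-10%."""
    variables = [
        ("economics.body_weight", 0.10),
        ("economics.body_surface_area", 0.10),
        ("economics.discount_rate_costs", 0.10),
        ("economics.discount_rate_effects", 0.10),
        ("biomarkers.egfr_prevalence", 0.10),
        ("utilities.u_pfs", 0.10),
        ("utilities.u_pd_active", 0.10),
        ("utilities.u_pd_bsc", 0.10),
        ("rebiopsy.biopsy_cost", 0.10),
        ("biomarkers.egfr_test_cost", 0.10),
        ("biomarkers.pdl1_test_cost", 0.10),
    ]
    variables += [(f"second_line.{name}.monthly_drug_cost", 0.10)
                  for name in sorted(params.second_line)]
    return variables


def one_way(params: ModelParameters,
            variables: Optional[Sequence[tuple[str, float]]] = None
            ) -> list[TornadoEntry]:
    """Two runs per variable (base x (1 - d), base x (1 + d)), sorted by span."""
    if variables is None:
        variables = default_tornado_variables(params)
    entries = []
    for path, delta in variables:
        base_value = get_by_path(params, path)
        if not isinstance(base_value, (int, float)) or isinstance(base_value, bool):
            raise TypeError(f"one-way variable {path!r} is not numeric")
        icurs = []
        for mult in (1.0 - delta, 1.0 + delta):
            p = params.model_copy(deep=True)
            set_by_path(p, path, base_value * mult)
            icurs.append(run_base_case(p).icur_per_qaly)
        span = (abs(icurs[1] - icurs[0])
                if None not in icurs else float("nan"))
        entries.append(TornadoEntry(path, 1.0 - delta, 1.0 + delta,
                                    icurs[0], icurs[1], span))
    entries.sort(key=lambda e: (-e.span if e.span == e.span else math.inf))
    return entries


# ---------------------------------------------------------------------------
# bivariate sensitivity/specificity grid


def bivariate_grid(params: ModelParameters,
                   deltas: Sequence[float] = (-0.03, -0.02, -0.01, 0.0,
                                              0.01, 0.02, 0.03)) -> pd.DataFrame:
    """QALY gain (testing vs no testing) when IHC and FISH accuracy move.

    Rows vary sensitivity, columns specificity, both by additive
    percentage-point deltas applied simultaneously to IHC and FISH and
    clamped to [0, 1].  Cell (0, 0) is the base case.
    """
    grid = np.empty((len(deltas), len(deltas)))
    for i, ds in enumerate(deltas):
        for j, dp in enumerate(deltas):
            p = params.model_copy(deep=True)
            for name in (StrategyName.IHC, StrategyName.FISH):
                st = p.strategy(name)
                st.sensitivity = min(1.0, max(0.0, st.sensitivity + ds))
                st.specificity = min(1.0, max(0.0, st.specificity + dp))
            grid[i, j] = run_base_case(p).d_qaly
    return pd.DataFrame(grid,
                        index=pd.Index(deltas, name="sensitivity_delta"),
                        columns=pd.Index(deltas, name="specificity_delta"))


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis (second-order Monte Carlo)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    if not 0 < mean < 1:
        raise ValueError(f"beta sampling needs mean in (0, 1), got {mean}")
    var = sd * sd
    max_var = mean * (1 - mean)
    if var >= max_var:
        raise ValueError("beta variance must be < mean(1-mean)")
    k = max_var / var - 1.0
    return mean * k, (1 - mean) * k


def _psa_parameter_plan(params: ModelParameters) -> list[tuple[str, str]]:
    """Sorted (path, family) pairs defining the PSA sampling order."""
    plan: list[tuple[str, str]] = []
    for f in ("u_pfs", "u_pd_active", "u_pd_bsc"):
        plan.append((f"utilities.{f}", "beta"))
    plan += [("economics.body_surface_area", "normal"),
             ("economics.body_weight", "normal")]
    for f in ("alk_prevalence", "egfr_prevalence", "ros1_prevalence",
              "pdl1_high_prevalence"):
        plan.append((f"biomarkers.{f}", "normal_prob"))
    plan.append(("rebiopsy.rebiopsy_probability", "normal_prob"))
    for st in params.strategies:
        plan.append((f"strategies.{st.name.value}.invalid_rate", "normal_prob"))
        if st.unit_cost is not None:
            plan.append((f"strategies.{st.name.value}.unit_cost", "gamma"))
    plan.append(("rebiopsy.biopsy_cost", "gamma"))
    for f in ("egfr_test_cost", "ros1_test_cost", "pdl1_test_cost"):
        plan.append((f"biomarkers.{f}", "gamma"))
    for name in sorted(params.treatments):
        plan.append((f"treatments.{name}.median_pfs", "normal_pos"))
        plan.append((f"treatments.{name}.median_os", "normal_pos"))
        plan.append((f"treatments.{name}.monthly_drug_cost_pfs", "gamma"))
        plan.append((f"treatments.{name}.admin_unit_cost", "gamma"))
    for name in sorted(params.second_line):
        plan.append((f"second_line.{name}.median_pfs_2l", "normal_pos"))
        plan.append((f"second_line.{name}.monthly_drug_cost", "gamma"))
        plan.append((f"second_line.{name}.admin_unit_cost", "gamma"))
    for f in ("median_pfs_fp", "median_os_fp"):
        plan.append((f"fp_adjustment.{f}", "normal_pos"))
    return plan


def _sample(rng: np.random.Generator, family: str, mean: float,
            rel_se: float) -> float:
    """Moment-matched draw; degenerate (the mean) at zero dispersion."""
    sd = rel_se * abs(mean)
    if sd == 0:
        return mean
    if family == "beta":
        a, b = _beta_params(mean, sd)
        return float(rng.beta(a, b))
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd * sd / mean
        return float(rng.gamma(shape, scale))
    x = float(rng.normal(mean, sd))
    if family == "normal_prob":
        return min(1.0, max(0.0, x))
    if family == "normal_pos":
        return max(1e-6, x)
    return x


@dataclass(frozen=True)
class PSAResult:
    n_draws: int
    seed: int
    draws: pd.DataFrame               # columns: d_cost, d_ly, d_qaly
    mean_d_cost: float
    mean_d_ly: float
    mean_d_qaly: float
    quadrant_shares: dict[str, float]

    def ceac(self, thresholds: Sequence[float]) -> pd.DataFrame:
        """P(testing cost-effective) against willingness-to-pay per QALY."""
        rows = [{"threshold": w,
                 "p_cost_effective": float(np.mean(
                     w * self.draws["d_qaly"] - self.draws["d_cost"] >= 0))}
                for w in thresholds]
        return pd.DataFrame(rows)


def run_psa(params: ModelParameters, n: Optional[int] = None,
            seed: Optional[int] = None) -> PSAResult:
    """Second-order Monte Carlo over all uncertain parameters.

    Each draw resamples every parameter in the plan from its family
    (moment-matched to the deterministic mean with SE = relative_se x
    mean), re-runs the full deterministic model and records the
    increments.  Test sensitivities/specificities are excluded (they are
    the subject of the bivariate analysis).  Reproducible given the seed.
    """
    n = params.psa.n_draws if n is None else n
    seed = params.psa.seed if seed is None else seed
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    plan = _psa_parameter_plan(params)
    means = [float(get_by_path(params, path)) for path, _ in plan]
    rel = params.psa.relative_se
    overrides = params.psa.relative_se_overrides

    rows = np.empty((n, 3))
    for k in range(n):
        p = params.model_copy(deep=True)
        for (path, family), mean in zip(plan, means):
            value = _sample(rng, family, mean, overrides.get(path, rel))
            set_by_path(p, path, value)
        r = run_base_case(p)
        rows[k] = (r.d_cost, r.d_ly, r.d_qaly)

    draws = pd.DataFrame(rows, columns=["d_cost", "d_ly", "d_qaly"])
    q = {
        "NE": float(np.mean((draws.d_qaly > 0) & (draws.d_cost > 0))),
        "SE": float(np.mean((draws.d_qaly > 0) & (draws.d_cost <= 0))),
        "NW": float(np.mean((draws.d_qaly <= 0) & (draws.d_cost > 0))),
        "SW": float(np.mean((draws.d_qaly <= 0) & (draws.d_cost <= 0))),
    }
    return PSAResult(n_draws=n, seed=seed, draws=draws,
                     mean_d_cost=float(draws.d_cost.mean()),
                     mean_d_ly=float(draws.d_ly.mean()),
                     mean_d_qaly=float(draws.d_qaly.mean()),
                     quadrant_shares=q)
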