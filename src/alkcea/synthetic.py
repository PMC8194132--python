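"""Synthetic parameter sets and stochastic/enumerative oracles.

Three independent cross-checks for the deterministic pipeline live here:

* :func:`generate_parameter_set` draws complete, internally consistent
  random parameter sets (probabilities in range, allocations summing to 1,
  PFS <= OS per arm) for property testing;
* :func:`microsimulate` is an individual-patient simulation of one arm
  with exact event times and closed-form discounting, the Monte-Carlo
  oracle for the cohort engine;
* :func:`enumerate_event_tree` walks every decision-tree path explicitly
  (strategy x validity x rebiopsy x truth x per-assay result), the exact
  oracle for :func:`alkcea.decision_tree.build_split`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .decision_tree import DiagnosticSplit
from .markov import exponential_rate, scaled_monthly_drug_cost, second_line_oneoff_cost
from .params import (
    AllocationTable,
    BiomarkerPanel,
    EconomicSettings,
    EpidemiologyInputs,
    FalsePositiveAdjustment,
    ModelParameters,
    MolecularGroup,
    Provenance,
    RebiopsyPolicy,
    SecondLineProfile,
    StrategyName,
    TestStrategy,
    TreatmentProfile,
    UtilitySet,
    iter_numeric_leaves,
)

__all__ = ["GeneratorConfig", "MicrosimEstimate", "generate_parameter_set",
           "microsimulate", "enumerate_event_tree"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ranges for the random parameter generator (months, euros, fractions)."""

    seed: int = 0
    accuracy_range: tuple[float, float] = (0.85, 1.0)
    invalid_range: tuple[float, float] = (0.0, 0.08)
    alk_prevalence_range: tuple[float, float] = (0.01, 0.08)
    egfr_prevalence_range: tuple[float, float] = (0.05, 0.20)
    ros1_prevalence_range: tuple[float, float] = (0.005, 0.04)
    pdl1_high_range: tuple[float, float] = (0.20, 0.50)
    median_pfs_range: tuple[float, float] = (2.0, 24.0)
    os_multiplier_range: tuple[float, float] = (1.2, 4.0)
    monthly_cost_range: tuple[float, float] = (500.0, 9000.0)
    assay_cost_range: tuple[float, float] = (50.0, 600.0)
    utility_pfs_range: tuple[float, float] = (0.6, 0.9)
    horizon_years_range: tuple[float, float] = (5.0, 20.0)
    discount_range: tuple[float, float] = (0.0, 0.05)
    arms_per_group: int = 2


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def generate_parameter_set(config: GeneratorConfig) -> ModelParameters:
    """Draw a complete random parameter set that passes validation."""
    rng = np.random.default_rng(config.seed)

    nonsq = float(rng.uniform(0.4, 0.9))
    epi = EpidemiologyInputs(
        lung_cancer_cases=float(rng.uniform(1_000, 50_000)),
        nsclc_share=float(rng.uniform(0.7, 0.95)),
        stage_iv_share=float(rng.uniform(0.3, 0.8)),
        nonsquamous_share=nonsq,
        squamous_share=1.0 - nonsq,
        squamous_never_smoker_share=float(rng.uniform(0.05, 0.3)),
        testing_rate=float(rng.uniform(0.5, 1.0)),
    )

    shares = rng.dirichlet(np.ones(4))
    def _strategy(name: StrategyName, share: float) -> TestStrategy:
        if name is StrategyName.REFLEX:
            return TestStrategy(name=name, share_of_patients=share,
                                invalid_rate=_uniform(rng, config.invalid_range))
        return TestStrategy(
            name=name, share_of_patients=share,
            sensitivity=_uniform(rng, config.accuracy_range),
            specificity=_uniform(rng, config.accuracy_range),
            invalid_rate=_uniform(rng, config.invalid_range),
            unit_cost=_uniform(rng, config.assay_cost_range))
    strategies = [_strategy(n, s) for n, s in
                  zip((StrategyName.IHC, StrategyName.FISH,
                       StrategyName.REFLEX, StrategyName.NGS), shares)]

    biomarkers = BiomarkerPanel(
        alk_prevalence=_uniform(rng, config.alk_prevalence_range),
        egfr_prevalence=_uniform(rng, config.egfr_prevalence_range),
        ros1_prevalence=_uniform(rng, config.ros1_prevalence_range),
        pdl1_high_prevalence=_uniform(rng, config.pdl1_high_range),
        egfr_test_cost=_uniform(rng, config.assay_cost_range),
        ros1_test_cost=_uniform(rng, config.assay_cost_range),
        pdl1_test_cost=_uniform(rng, config.assay_cost_range))

    rebiopsy = RebiopsyPolicy(
        rebiopsy_probability=float(rng.uniform(0, 1)),
        biopsy_cost=float(rng.uniform(100, 800)), max_repeats=1)

    second_line = {}
    treatments: dict[str, TreatmentProfile] = {}
    alloc_bc: dict[MolecularGroup, dict[str, float]] = {}
    alloc_sa: dict[MolecularGroup, dict[str, float]] = {}
    for group in MolecularGroup:
        sl_name = f"sl_{group.value.lower()}"
        second_line[sl_name] = SecondLineProfile(
            name=sl_name,
            share_active_treatment=float(rng.uniform(0.3, 0.9)),
            median_pfs_2l=float(rng.uniform(2.0, 8.0)),
            monthly_drug_cost=float(rng.uniform(500, 5000)),
            admin_unit_cost=float(rng.uniform(0, 300)))
        names = []
        for k in range(config.arms_per_group):
            name = f"tx_{group.value.lower()}_{k}"
            pfs = _uniform(rng, config.median_pfs_range)
            treatments[name] = TreatmentProfile(
                name=name, molecular_group=group,
                median_pfs=pfs,
                median_os=pfs * _uniform(rng, config.os_multiplier_range),
                monthly_drug_cost_pfs=_uniform(rng, config.monthly_cost_range),
                iv_administrations_per_cycle=float(rng.integers(0, 2)),
                admin_unit_cost=float(rng.uniform(100, 300)),
                second_line_link=sl_name,
                bsa_scaled_fraction=float(rng.uniform(0, 0.5)),
                weight_scaled_fraction=float(rng.uniform(0, 0.3)))
            names.append(name)
        for table in (alloc_bc, alloc_sa):
            w = rng.dirichlet(np.ones(len(names)))
            table[group] = {n: float(x) for n, x in zip(names, w)}

    u_pfs = _uniform(rng, config.utility_pfs_range)
    u_pd_active = float(rng.uniform(0.3, u_pfs))
    utilities = UtilitySet(u_pfs=u_pfs, u_pd_active=u_pd_active,
                           u_pd_bsc=float(rng.uniform(0.2, u_pd_active)))

    economics = EconomicSettings(
        discount_rate_costs=_uniform(rng, config.discount_range),
        discount_rate_effects=_uniform(rng, config.discount_range),
        horizon_years=_uniform(rng, config.horizon_years_range),
        cycle_length_months=1.0,
        body_surface_area=float(rng.uniform(1.5, 2.1)),
        body_weight=float(rng.uniform(55, 95)))

    stop = float(rng.uniform(4, 8)) if rng.uniform() < 0.7 else None
    fp_adj = FalsePositiveAdjustment(
        median_pfs_fp=float(rng.uniform(1.0, 4.0)),
        stopping_rule_month=stop,
        median_os_fp=float(rng.uniform(10.0, 24.0)))

    wt_low = list(alloc_bc[MolecularGroup.WT_TPS_LOW])
    mix_w = rng.dirichlet(np.ones(len(wt_low)))
    no_testing_mix = {n: float(x) for n, x in zip(wt_low, mix_w)}

    params = ModelParameters(
        epidemiology=epi, strategies=strategies, biomarkers=biomarkers,
        rebiopsy=rebiopsy, treatments=treatments, second_line=second_line,
        allocations={
            "base_case": AllocationTable(name="base_case", shares=alloc_bc),
            "alternative": AllocationTable(name="alternative", shares=alloc_sa)},
        allocation_variant="base_case", utilities=utilities,
        economics=economics, fp_adjustment=fp_adj,
        no_testing_mix=no_testing_mix,
        metadata={"generator_seed": str(config.seed)})
    params.provenance.update({path: Provenance.USER.value
                              for path, _ in iter_numeric_leaves(params)})
    return params


# ---------------------------------------------------------------------------
# individual-patient microsimulation


@dataclass(frozen=True)
class MicrosimEstimate:
    n_patients: int
    seed: int
    mean_ly: float
    se_ly: float
    mean_qaly: float
    se_qaly: float
    mean_cost: float
    se_cost: float


def _disc_integral(x: np.ndarray, rho: float) -> np.ndarray:
    """Integral of exp(-rho t) from 0 to x, elementwise."""
    if rho == 0:
        return x
    return (1.0 - np.exp(-rho * x)) / rho


def microsimulate(profile: TreatmentProfile, utilities: UtilitySet,
                  second_line: Optional[SecondLineProfile],
                  settings: EconomicSettings, n: int, seed: int,
                  include_second_line_cost: bool = True) -> MicrosimEstimate:
    """Simulate n patients on one arm with exact event times.

    One latent uniform per patient drives both the progression and the
    death time (comonotone coupling), matching the partitioned-survival
    identity PFS = min(S_pfs, S_os) used by the cohort engine.  Outcomes
    are discounted in continuous time with rho = ln(1 + r)/12 per month,
    identical to the cohort engine's cycle-boundary factors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lam_os = exponential_rate(profile.median_os)
    lam_pfs = max(exponential_rate(profile.median_pfs), lam_os)
    horizon = settings.horizon_years * 12.0

    u = rng.uniform(size=n)
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    t_death = -np.log(u) / lam_os
    t_prog_cand = -np.log(u) / lam_pfs
    if profile.pfs_stopping_rule_month is not None:
        t_prog_cand = np.minimum(t_prog_cand, profile.pfs_stopping_rule_month)
    progressed = t_prog_cand < t_death

    e = np.minimum(t_death, horizon)                 # time alive in model
    a = np.minimum(np.minimum(t_prog_cand, t_death), horizon)  # time in PFS

    rho_eff = math.log1p(settings.discount_rate_effects) / 12.0
    rho_cost = math.log1p(settings.discount_rate_costs) / 12.0

    d_a = _disc_integral(a, rho_eff)
    d_e = _disc_integral(e, rho_eff)
    ly = d_e / 12.0

    share_active = second_line.share_active_treatment if second_line else 0.0
    u_pd = (share_active * utilities.u_pd_active
            + (1.0 - share_active) * utilities.u_pd_bsc)
    qaly = (utilities.u_pfs * d_a + u_pd * (d_e - d_a)) / 12.0

    monthly = (scaled_monthly_drug_cost(profile, settings)
               + profile.iv_administrations_per_cycle * profile.admin_unit_cost
               / settings.cycle_length_months)
    cost = monthly * _disc_integral(a, rho_cost)
    if include_second_line_cost and second_line is not None:
        oneoff = second_line_oneoff_cost(second_line)
        pays = progressed & (t_prog_cand < horizon)
        cost = cost + np.where(pays, oneoff * np.exp(-rho_cost * t_prog_cand), 0.0)

    def mse(x: np.ndarray) -> tuple[float, float]:
        m = float(np.mean(x))
        se = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return m, se

    m_ly, se_ly = mse(ly)
    m_q, se_q = mse(qaly)
    m_c, se_c = mse(cost)
    return MicrosimEstimate(n_patients=n, seed=seed, mean_ly=m_ly, se_ly=se_ly,
                            mean_qaly=m_q, se_qaly=se_q,
                            mean_cost=m_c, se_cost=se_c)


# ---------------------------------------------------------------------------
# brute-force decision-tree enumerator


def enumerate_event_tree(params: ModelParameters) -> DiagnosticSplit:
    """Exact path-by-path enumeration of the diagnostic decision tree.

    Expands every (strategy, validity, rebiopsy, truth, assay result)
    path explicitly -- reflex testing is expanded over the IHC result and
    the conditional FISH result rather than through the serial-composition
    formulas -- and accumulates classification masses and expected costs.
    Serves as the independent ground truth for
    :func:`alkcea.decision_tree.build_split`.
    """
    b = params.biomarkers
    p = b.alk_prevalence
    ihc = params.strategy(StrategyName.IHC)
    fish = params.strategy(StrategyName.FISH)
    sequential = params.diagnosis_mode == "sequential"
    alk_share = (1.0 - b.egfr_prevalence) if sequential else 1.0
    q_given_neg = b.egfr_prevalence / (1.0 - p) if p < 1 else 0.0

    # accumulators
    mass = {"TP": 0.0, "FP": 0.0, "TN": 0.0, "FN": 0.0, "UNTESTED": 0.0}
    assay_cost = 0.0
    biopsy_cost = 0.0

    def classify_paths(strategy: TestStrategy) -> list[tuple[float, str, float]]:
        """(probability, classification, assay cost) for one interpretable assay."""
        out: list[tuple[float, str, float]] = []
        if strategy.name is StrategyName.REFLEX:
            c_i, c_f = ihc.unit_cost, fish.unit_cost
            for truth_p, is_alk in ((p, True), (1 - p, False)):
                p_ihc_pos = ihc.sensitivity if is_alk else 1 - ihc.specificity
                # IHC negative: final negative, no FISH billed
                cls = "FN" if is_alk else "TN"
                out.append((truth_p * (1 - p_ihc_pos), cls, c_i))
                # IHC positive: FISH confirmation
                p_fish_pos = fish.sensitivity if is_alk else 1 - fish.specificity
                cls_pos = "TP" if is_alk else "FP"
                cls_neg = "FN" if is_alk else "TN"
                out.append((truth_p * p_ihc_pos * p_fish_pos, cls_pos, c_i + c_f))
                out.append((truth_p * p_ihc_pos * (1 - p_fish_pos), cls_neg, c_i + c_f))
            return out
        se, sp, c = strategy.sensitivity, strategy.specificity, strategy.unit_cost
        out.append((p * se, "TP", c))
        out.append((p * (1 - se), "FN", c))
        out.append(((1 - p) * (1 - sp), "FP", c))
        out.append(((1 - p) * sp, "TN", c))
        return out

    for st in params.strategies:
        w = st.share_of_patients
        if w == 0:
            continue
        # expected cost of one assay attempt (invalid attempts are billed at
        # the expected composition, matching the cohort costing convention)
        attempt_paths = classify_paths(st)
        attempt_cost = sum(pr * c for pr, _, c in attempt_paths)

        i = st.invalid_rate
        rb = params.rebiopsy.rebiopsy_probability
        # valid on the first attempt
        for pr, cls, c in attempt_paths:
            mass[cls] += w * (1 - i) * pr
            assay_cost += w * (1 - i) * pr * c * alk_share
        # invalid -> rebiopsy -> repeat assay (assumed interpretable)
        for pr, cls, c in attempt_paths:
            mass[cls] += w * i * rb * pr
            assay_cost += w * i * rb * pr * (attempt_cost + c) * alk_share
        biopsy_cost += w * i * rb * params.rebiopsy.biopsy_cost * alk_share
        # invalid -> no rebiopsy -> chemotherapy without a result
        mass["UNTESTED"] += w * i * (1 - rb)
        assay_cost += w * i * (1 - rb) * attempt_cost * alk_share

    resolved = mass["TP"] + mass["FP"] + mass["TN"] + mass["FN"]
    if sequential:
        egfr_mass = 1.0
        ros1_mass = mass["TN"] * (1.0 - q_given_neg) + mass["FN"]
    else:
        egfr_mass = mass["TN"] + mass["FN"]
        ros1_mass = mass["TN"] + mass["FN"]
    companion = (b.egfr_test_cost * egfr_mass + b.ros1_test_cost * ros1_mass
                 + b.pdl1_test_cost * resolved)

    return DiagnosticSplit(
        tp=mass["TP"], fp=mass["FP"], tn=mass["TN"], fn=mass["FN"],
        untested_chemo=mass["UNTESTED"],
        expected_testing_cost=assay_cost + companion,
        expected_biopsy_cost=biopsy_cost)
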