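"""Diagnostic decision tree: from the national strategy mix to a
classification split and a treatment-arm distribution.

Each tested patient goes through one of four ALK-determination strategies
(IHC, FISH, reflex = IHC with FISH confirmation of positives, NGS).  An
invalid assay triggers a rebiopsy with probability 77.1%, after which the
repeat assay is assumed interpretable; without rebiopsy the patient starts
chemotherapy with no molecular result.  Interpretable results classify as
TP / FP / TN / FN from the ALK prevalence and the strategy's sensitivity
and specificity.  Negative patients cascade through the companion panel
(EGFR, then ROS1, then PD-L1 TPS) to a treatment group.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .params import (
    AllocationTable,
    BiomarkerPanel,
    ModelParameters,
    MolecularGroup,
    RebiopsyPolicy,
    StrategyName,
    TestStrategy,
)

__all__ = [
    "TruthStatus",
    "DiagnosticSplit",
    "ArmEntry",
    "ArmDistribution",
    "classification_probabilities",
    "strategy_accuracy",
    "resolve_invalids",
    "build_split",
    "allocate_treatments",
    "no_testing_allocation",
]


class TruthStatus(str, enum.Enum):
    """True molecular status relative to the arm a patient lands in.

    ``ALK_MISSED`` marks truly ALK-positive patients treated on
    non-targeted curves (false negatives and the untested / no-testing
    ALK-positive share): their effectiveness is the non-targeted arm's,
    but they are accountable as missed ALK cases.
    """

    ALK_TP = "ALK_TP"
    ALK_FP = "ALK_FP"
    ALK_MISSED = "ALK_MISSED"
    NON_ALK = "NON_ALK"


@dataclass(frozen=True)
class DiagnosticSplit:
    """Cohort fractions over diagnostic outcomes plus expected costs.

    ``untested_chemo`` is the fraction starting chemotherapy with no
    molecular result (invalid assay, no rebiopsy).  Costs are expected
    euros per tested patient: ``expected_testing_cost`` covers ALK assays
    (including repeats) and companion tests, ``expected_biopsy_cost`` the
    rebiopsy procedure itself.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    untested_chemo: float
    expected_testing_cost: float
    expected_biopsy_cost: float

    @property
    def resolved(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def total_expected_cost(self) -> float:
        return self.expected_testing_cost + self.expected_biopsy_cost


@dataclass(frozen=True)
class ArmEntry:
    treatment: str
    truth: TruthStatus
    fraction: float


@dataclass(frozen=True)
class ArmDistribution:
    entries: tuple[ArmEntry, ...]

    def total(self) -> float:
        return sum(e.fraction for e in self.entries)


def classification_probabilities(prevalence: float, sensitivity: float,
                                 specificity: float) -> tuple[float, float, float, float]:
    """(TP, FP, TN, FN) fractions for a binary test on one population.

    TP = prevalence * sensitivity; FP = (1 - prevalence) * (1 - specificity);
    TN = (1 - prevalence) * specificity; FN = prevalence * (1 - sensitivity).
    """
    for name, x in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not 0 <= x <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {x}")
    tp = prevalence * sensitivity
    fp = (1 - prevalence) * (1 - specificity)
    tn = (1 - prevalence) * specificity
    fn = prevalence * (1 - sensitivity)
    return tp, fp, tn, fn


def strategy_accuracy(strategy: TestStrategy, ihc: TestStrategy,
                      fish: TestStrategy, prevalence: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, expected assay cost) for one strategy.

    Reflex testing confirms IHC positives by FISH, so a patient is
    reflex-positive only if both assays are positive (serial composition):
    Se = Se_IHC * Se_FISH and Sp = 1 - (1 - Sp_IHC)(1 - Sp_FISH).  Its
    expected cost is the IHC assay plus FISH for the IHC-positive fraction
    P(IHC+) = p*Se_IHC + (1-p)(1-Sp_IHC).
    """
    if strategy.name is StrategyName.REFLEX:
        se = ihc.sensitivity * fish.sensitivity
        sp = 1.0 - (1.0 - ihc.specificity) * (1.0 - fish.specificity)
        p_ihc_pos = (prevalence * ihc.sensitivity
                     + (1 - prevalence) * (1 - ihc.specificity))
        cost = ihc.unit_cost + p_ihc_pos * fish.unit_cost
        return se, sp, cost
    if strategy.name in (StrategyName.IHC, StrategyName.FISH, StrategyName.NGS):
        return strategy.sensitivity, strategy.specificity, strategy.unit_cost
    raise ValueError(f"unknown strategy {strategy.name!r}")


def resolve_invalids(strategy: TestStrategy, policy: RebiopsyPolicy,
                     repeat_assay_cost: float) -> tuple[float, float, float]:
    """Handle invalid assays: returns (resolved, untested, added expected cost).

    A single rebiopsy loop is modelled: the repeat assay after rebiopsy is
    assumed interpretable, so ``untested = invalid_rate * (1 - rebiopsy
    probability)`` and the expected added cost per patient is
    ``invalid_rate * rebiopsy_probability * (biopsy + repeat assay)``.
    """
    untested = strategy.invalid_rate * (1.0 - policy.rebiopsy_probability)
    resolved = 1.0 - untested
    added = (strategy.invalid_rate * policy.rebiopsy_probability
             * (policy.biopsy_cost + repeat_assay_cost))
    return resolved, untested, added


def build_split(params: ModelParameters) -> DiagnosticSplit:
    """Mix the four strategies into one cohort-level diagnostic split.

    Companion-test costing follows the configured ``diagnosis_mode``:

    * ``parallel`` (base case): the ALK assay runs for everyone; EGFR and
      ROS1 are billed to patients with an ALK-negative result; PD-L1 to
      every patient with an interpretable result.
    * ``sequential``: EGFR is tested first on everyone, truly EGFR-positive
      patients skip the ALK assay (and its invalid/rebiopsy costs), ROS1 is
      billed to EGFR-negative patients with an ALK-negative result, PD-L1
      to all with an interpretable result.  Classification fractions are
      unchanged: the mode is a costing convention for assay timing.
    """
    b = params.biomarkers
    p = b.alk_prevalence
    ihc = params.strategy(StrategyName.IHC)
    fish = params.strategy(StrategyName.FISH)

    sequential = params.diagnosis_mode == "sequential"
    # fraction of patients who never reach the ALK assay in sequential mode
    alk_assay_share = (1.0 - b.egfr_prevalence) if sequential else 1.0

    tp = fp = tn = fn = untested = 0.0
    assay_cost = biopsy_cost = 0.0
    for st in params.strategies:
        w = st.share_of_patients
        if w == 0:
            continue
        se, sp, cost = strategy_accuracy(st, ihc, fish, p)
        resolved, unt, added = resolve_invalids(st, params.rebiopsy, cost)
        ctp, cfp, ctn, cfn = classification_probabilities(p, se, sp)
        tp += w * resolved * ctp
        fp += w * resolved * cfp
        tn += w * resolved * ctn
        fn += w * resolved * cfn
        untested += w * unt
        repeat_assay = (st.invalid_rate * params.rebiopsy.rebiopsy_probability
                        * cost)
        assay_cost += w * (cost + repeat_assay) * alk_assay_share
        biopsy_cost += (w * st.invalid_rate
                        * params.rebiopsy.rebiopsy_probability
                        * params.rebiopsy.biopsy_cost * alk_assay_share)

    resolved_total = tp + fp + tn + fn
    if sequential:
        # EGFR first for everyone entering diagnosis; ROS1 only for
        # EGFR-negatives whose ALK result is negative (TN patients are
        # truly ALK-negative, of whom egfr_prev/(1-p) are EGFR-positive;
        # FN patients are truly ALK-positive, EGFR forced negative).
        egfr_mass = 1.0
        q_given_alk_neg = b.egfr_prevalence / (1.0 - p) if p < 1 else 0.0
        ros1_mass = tn * (1.0 - q_given_alk_neg) + fn
    else:
        egfr_mass = tn + fn
        ros1_mass = tn + fn
    companion = (b.egfr_test_cost * egfr_mass
                 + b.ros1_test_cost * ros1_mass
                 + b.pdl1_test_cost * resolved_total)

    return DiagnosticSplit(
        tp=tp, fp=fp, tn=tn, fn=fn, untested_chemo=untested,
        expected_testing_cost=assay_cost + companion,
        expected_biopsy_cost=biopsy_cost)


def _split_mix(mix: dict[str, float]) -> dict[str, float]:
    """Renormalize a treatment mix so shares sum to exactly 1.

    Printed allocation columns can be off by rounding (e.g. 89.38% +
    10.63% = 100.01%); stored values stay verbatim, renormalisation
    happens here so cohort fractions are exact.
    """
    tot = sum(mix.values())
    if tot <= 0:
        raise ValueError("treatment mix has no positive share")
    return {k: v / tot for k, v in mix.items()}


def allocate_treatments(split: DiagnosticSplit, panel: BiomarkerPanel,
                        alloc: AllocationTable,
                        no_testing_mix: dict[str, float]) -> ArmDistribution:
    """Distribute the tested cohort over first-line treatment arms.

    ALK-positive results (TP and FP) go to the ALK-targeted mix.  Negative
    results cascade through the companion panel with marginal positivity
    rates renormalised among ALK-negatives (drivers are mutually
    exclusive): EGFR, then ROS1 among EGFR-negatives, then PD-L1 TPS >= 50%
    among panel-negatives.  False negatives are truly ALK-positive, so
    their EGFR/ROS1 determinations are forced negative and only the PD-L1
    split applies; they keep non-targeted effectiveness but are flagged
    ``ALK_MISSED``.  Untested patients receive the no-testing mix.
    """
    entries: list[ArmEntry] = []

    def extend(mass: float, group: MolecularGroup, truth: TruthStatus) -> None:
        if mass <= 0:
            return
        for tr, share in _split_mix(alloc.arms(group)).items():
            entries.append(ArmEntry(tr, truth, mass * share))

    # ALK-positive results
    extend(split.tp, MolecularGroup.ALK, TruthStatus.ALK_TP)
    extend(split.fp, MolecularGroup.ALK, TruthStatus.ALK_FP)

    p = panel.alk_prevalence
    # true negatives: full companion cascade (conditional prevalences)
    q_egfr = panel.egfr_prevalence / (1.0 - p) if p < 1 else 0.0
    rem_prev = 1.0 - p - panel.egfr_prevalence
    q_ros1 = panel.ros1_prevalence / rem_prev if rem_prev > 0 else 0.0
    tn = split.tn
    extend(tn * q_egfr, MolecularGroup.EGFR, TruthStatus.NON_ALK)
    tn_after_egfr = tn * (1.0 - q_egfr)
    extend(tn_after_egfr * q_ros1, MolecularGroup.ROS1, TruthStatus.NON_ALK)
    tn_wt = tn_after_egfr * (1.0 - q_ros1)
    extend(tn_wt * panel.pdl1_high_prevalence,
           MolecularGroup.WT_TPS_HIGH, TruthStatus.NON_ALK)
    extend(tn_wt * (1.0 - panel.pdl1_high_prevalence),
           MolecularGroup.WT_TPS_LOW, TruthStatus.NON_ALK)

    # false negatives: EGFR/ROS1 forced negative, PD-L1 still informative
    extend(split.fn * panel.pdl1_high_prevalence,
           MolecularGroup.WT_TPS_HIGH, TruthStatus.ALK_MISSED)
    extend(split.fn * (1.0 - panel.pdl1_high_prevalence),
           MolecularGroup.WT_TPS_LOW, TruthStatus.ALK_MISSED)

    # invalid without rebiopsy: chemotherapy without a molecular result
    if split.untested_chemo > 0:
        for tr, share in _split_mix(no_testing_mix).items():
            mass = split.untested_chemo * share
            entries.append(ArmEntry(tr, TruthStatus.ALK_MISSED, mass * p))
            entries.append(ArmEntry(tr, TruthStatus.NON_ALK, mass * (1 - p)))

    return ArmDistribution(entries=tuple(entries))


def no_testing_allocation(params: ModelParameters) -> ArmDistribution:
    """Distribute the whole cohort over the non-targeted no-testing mix.

    ALK-positive patients (prevalence share) are flagged ``ALK_MISSED``:
    they sit on non-targeted survival curves, but remain identifiable.
    """
    p = params.biomarkers.alk_prevalence
    entries: list[ArmEntry] = []
    for tr, share in _split_mix(params.no_testing_mix).items():
        if p > 0:
            entries.append(ArmEntry(tr, TruthStatus.ALK_MISSED, share * p))
        entries.append(ArmEntry(tr, TruthStatus.NON_ALK, share * (1 - p)))
    return ArmDistribution(entries=tuple(entries))
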