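"""Parameter schema, validation and (de)serialisation for the ALK-testing model.

The model is driven by one :class:`ModelParameters` object bundling the
epidemiology cascade, the diagnostic strategy mix, biomarker positivity
rates, treatment profiles with their second-line linkage, utilities and
economic settings.  All probabilities are stored as fractions in [0, 1];
percentages belong to the display layer.  All monetary values are plain
euro decimals of a single price year (recorded in metadata).

Every numeric leaf carries a provenance tag: ``paper`` for values printed
in the source publication, ``external-fixture`` for values the publication
sourced from trials/price lists without printing them (shipped here as
clearly labelled placeholders), and ``user`` for anything else.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "StrategyName",
    "MolecularGroup",
    "Provenance",
    "EpidemiologyInputs",
    "TestStrategy",
    "BiomarkerPanel",
    "RebiopsyPolicy",
    "TreatmentProfile",
    "SecondLineProfile",
    "AllocationTable",
    "UtilitySet",
    "EconomicSettings",
    "FalsePositiveAdjustment",
    "PSASettings",
    "ModelParameters",
    "Violation",
    "validate",
    "load_parameters",
    "write_parameters",
    "iter_numeric_leaves",
]


class StrategyName(str, enum.Enum):
    IHC = "IHC"
    FISH = "FISH"
    REFLEX = "REFLEX"
    NGS = "NGS"


class MolecularGroup(str, enum.Enum):
    """Molecular result groups that gate first-line treatment choice."""

    ALK = "ALK"
    EGFR = "EGFR"
    ROS1 = "ROS1"
    WT_TPS_HIGH = "WT_TPS_HIGH"   # wild-type, PD-L1 TPS >= 50%
    WT_TPS_LOW = "WT_TPS_LOW"     # wild-type, PD-L1 TPS < 50%


class Provenance(str, enum.Enum):
    PAPER = "paper"
    EXTERNAL_FIXTURE = "external-fixture"
    USER = "user"


class _Base(BaseModel):
    model_config = ConfigDict(validate_assignment=False, extra="forbid")


class EpidemiologyInputs(_Base):
    """Annual incident-population cascade fractions (national level)."""

    lung_cancer_cases: float = Field(gt=0)
    nsclc_share: float = Field(ge=0, le=1)
    stage_iv_share: float = Field(ge=0, le=1)
    nonsquamous_share: float = Field(ge=0, le=1)
    squamous_share: float = Field(ge=0, le=1)
    squamous_never_smoker_share: float = Field(ge=0, le=1)
    testing_rate: float = Field(ge=0, le=1)


class TestStrategy(_Base):
    """One ALK-determination strategy in the national mix.

    For REFLEX (IHC with FISH confirmation of positives) the accuracy and
    cost are derived from the IHC and FISH components, so its own
    ``sensitivity``/``specificity``/``unit_cost`` are ``None``.
    """

    name: StrategyName
    share_of_patients: float = Field(ge=0, le=1)
    sensitivity: Optional[float] = Field(default=None, ge=0, le=1)
    specificity: Optional[float] = Field(default=None, ge=0, le=1)
    invalid_rate: float = Field(ge=0, le=1)
    unit_cost: Optional[float] = Field(default=None, ge=0)


class BiomarkerPanel(_Base):
    """Marginal positivity rates and companion-test unit costs."""

    alk_prevalence: float = Field(ge=0, le=1)
    egfr_prevalence: float = Field(ge=0, le=1)
    ros1_prevalence: float = Field(ge=0, le=1)
    pdl1_high_prevalence: float = Field(ge=0, le=1)
    egfr_test_cost: float = Field(ge=0)
    ros1_test_cost: float = Field(ge=0)
    pdl1_test_cost: float = Field(ge=0)


class RebiopsyPolicy(_Base):
    rebiopsy_probability: float = Field(ge=0, le=1)
    biopsy_cost: float = Field(ge=0)
    max_repeats: int = Field(default=1, ge=1)


class TreatmentProfile(_Base):
    """One first-line arm: exponential survival summaries plus cost structure.

    ``monthly_drug_cost_pfs`` is the acquisition cost per model cycle at the
    reference body surface area / weight; ``bsa_scaled_fraction`` and
    ``weight_scaled_fraction`` say what share of that cost scales linearly
    with BSA and weight (dose-dependent IV drugs), the remainder being flat
    (oral TKIs, flat-dose antibodies).
    """

    name: str
    molecular_group: MolecularGroup
    median_pfs: float = Field(gt=0)
    median_os: float = Field(gt=0)
    monthly_drug_cost_pfs: float = Field(ge=0)
    iv_administrations_per_cycle: float = Field(default=0.0, ge=0)
    admin_unit_cost: float = Field(default=0.0, ge=0)
    second_line_link: Optional[str] = None
    pfs_stopping_rule_month: Optional[float] = Field(default=None, gt=0)
    bsa_scaled_fraction: float = Field(default=0.0, ge=0, le=1)
    weight_scaled_fraction: float = Field(default=0.0, ge=0, le=1)


class SecondLineProfile(_Base):
    """Second-line treatment entered as a one-off cost at progression."""

    name: str
    share_active_treatment: float = Field(ge=0, le=1)  # remainder gets BSC
    median_pfs_2l: float = Field(gt=0)
    monthly_drug_cost: float = Field(ge=0)
    admin_unit_cost: float = Field(default=0.0, ge=0)


class AllocationTable(_Base):
    """Distribution of treatments within each molecular result group."""

    name: str
    shares: dict[MolecularGroup, dict[str, float]]

    def arms(self, group: MolecularGroup) -> dict[str, float]:
        try:
            return self.shares[group]
        except KeyError:
            raise KeyError(f"allocation table {self.name!r} has no entry for "
                           f"molecular group {group.value!r}") from None


class UtilitySet(_Base):
    u_pfs: float = Field(ge=0, le=1)
    u_pd_active: float = Field(ge=0, le=1)
    u_pd_bsc: float = Field(ge=0, le=1)


class EconomicSettings(_Base):
    discount_rate_costs: float = Field(ge=0)     # per year
    discount_rate_effects: float = Field(ge=0)   # per year
    horizon_years: float = Field(gt=0)
    cycle_length_months: float = Field(default=1.0, gt=0)
    body_surface_area: float = Field(gt=0)       # m^2
    body_weight: float = Field(gt=0)             # kg
    reference_bsa: float = Field(default=1.81, gt=0)
    reference_weight: float = Field(default=72.885, gt=0)
    vial_sharing: bool = True


class FalsePositiveAdjustment(_Base):
    """Survival overrides for ALK false positives on targeted therapy."""

    median_pfs_fp: float = Field(gt=0)
    stopping_rule_month: Optional[float] = Field(default=None, gt=0)
    median_os_fp: float = Field(gt=0)


class PSASettings(_Base):
    n_draws: int = Field(default=1000, ge=1)
    seed: int = Field(default=20210610)
    relative_se: float = Field(default=0.10, ge=0)
    # optional per-parameter-path relative SE overrides
    relative_se_overrides: dict[str, float] = Field(default_factory=dict)


class ModelParameters(_Base):
    """Complete, validated input set for one model run."""

    epidemiology: EpidemiologyInputs
    strategies: list[TestStrategy]
    biomarkers: BiomarkerPanel
    rebiopsy: RebiopsyPolicy
    treatments: dict[str, TreatmentProfile]
    second_line: dict[str, SecondLineProfile]
    allocations: dict[str, AllocationTable]
    allocation_variant: str = "base_case"
    utilities: UtilitySet
    economics: EconomicSettings
    fp_adjustment: FalsePositiveAdjustment
    psa: PSASettings = Field(default_factory=PSASettings)
    diagnosis_mode: str = "parallel"            # parallel | sequential
    include_second_line: bool = True
    no_testing_mix: dict[str, float] = Field(default_factory=dict)
    provenance: dict[str, str] = Field(default_factory=dict)
    metadata: dict[str, str] = Field(default_factory=dict)

    @field_validator("diagnosis_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("parallel", "sequential"):
            raise ValueError("diagnosis_mode must be 'parallel' or 'sequential'")
        return v

    def strategy(self, name: Union[str, StrategyName]) -> TestStrategy:
        name = StrategyName(name)
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name.value!r}")

    def allocation(self) -> AllocationTable:
        return self.allocations[self.allocation_variant]


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    field: str
    value: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r} violates: {self.rule}"


_SHARE_TOL = 1e-9
_ALLOC_TOL = 1e-3  # printed allocation columns may sum to 100.01%


def validate(params: ModelParameters) -> list[Violation]:
    """Return all invariant violations (empty list means the set is valid).

    Range checks duplicated from the field constraints are re-run here so
    that programmatically constructed or mutated objects are also covered.
    """
    v: list[Violation] = []
    epi = params.epidemiology

    def chk(cond: bool, field: str, value: object, rule: str) -> None:
        if not cond:
            v.append(Violation(field, value, rule))

    # epidemiology
    for f in ("nsclc_share", "stage_iv_share", "nonsquamous_share",
              "squamous_share", "squamous_never_smoker_share", "testing_rate"):
        x = getattr(epi, f)
        chk(0 <= x <= 1, f"epidemiology.{f}", x, "fraction in [0, 1]")
    chk(epi.lung_cancer_cases > 0, "epidemiology.lung_cancer_cases",
        epi.lung_cancer_cases, "> 0")
    s = epi.nonsquamous_share + epi.squamous_share
    chk(abs(s - 1.0) <= _SHARE_TOL, "epidemiology.nonsquamous_share+squamous_share",
        s, "histology shares sum to 1")

    # strategies
    total_share = 0.0
    seen: set[StrategyName] = set()
    for st in params.strategies:
        pre = f"strategies.{st.name.value}"
        total_share += st.share_of_patients
        chk(st.name not in seen, pre, st.name.value, "strategy listed once")
        seen.add(st.name)
        chk(0 <= st.share_of_patients <= 1, f"{pre}.share_of_patients",
            st.share_of_patients, "fraction in [0, 1]")
        chk(0 <= st.invalid_rate <= 1, f"{pre}.invalid_rate",
            st.invalid_rate, "fraction in [0, 1]")
        if st.name is StrategyName.REFLEX:
            continue
        for f in ("sensitivity", "specificity"):
            x = getattr(st, f)
            chk(x is not None and 0 <= x <= 1, f"{pre}.{f}", x,
                "required fraction in [0, 1] for non-reflex strategy")
        chk(st.unit_cost is not None and st.unit_cost >= 0,
            f"{pre}.unit_cost", st.unit_cost, "required cost >= 0")
    chk(abs(total_share - 1.0) <= _SHARE_TOL, "strategies[*].share_of_patients",
        total_share, "strategy shares sum to 1")
    if StrategyName.REFLEX in seen:
        chk(StrategyName.IHC in seen and StrategyName.FISH in seen,
            "strategies", sorted(s.value for s in seen),
            "REFLEX requires IHC and FISH components")

    # biomarkers
    b = params.biomarkers
    for f in ("alk_prevalence", "egfr_prevalence", "ros1_prevalence",
              "pdl1_high_prevalence"):
        x = getattr(b, f)
        chk(0 <= x <= 1, f"biomarkers.{f}", x, "fraction in [0, 1]")
    for f in ("egfr_test_cost", "ros1_test_cost", "pdl1_test_cost"):
        chk(getattr(b, f) >= 0, f"biomarkers.{f}", getattr(b, f), "cost >= 0")
    marg = b.alk_prevalence + b.egfr_prevalence + b.ros1_prevalence
    chk(marg < 1, "biomarkers", marg,
        "mutually exclusive driver prevalences must sum to < 1")

    # rebiopsy
    chk(0 <= params.rebiopsy.rebiopsy_probability <= 1,
        "rebiopsy.rebiopsy_probability", params.rebiopsy.rebiopsy_probability,
        "fraction in [0, 1]")
    chk(params.rebiopsy.biopsy_cost >= 0, "rebiopsy.biopsy_cost",
        params.rebiopsy.biopsy_cost, "cost >= 0")
    chk(params.rebiopsy.max_repeats >= 1, "rebiopsy.max_repeats",
        params.rebiopsy.max_repeats, ">= 1")

    # treatments
    for name, t in params.treatments.items():
        pre = f"treatments.{name}"
        chk(t.median_pfs > 0, f"{pre}.median_pfs", t.median_pfs, "> 0")
        chk(t.median_os > 0, f"{pre}.median_os", t.median_os, "> 0")
        chk(t.median_pfs <= t.median_os, f"{pre}.median_pfs", t.median_pfs,
            "median_pfs <= median_os")
        chk(t.monthly_drug_cost_pfs >= 0, f"{pre}.monthly_drug_cost_pfs",
            t.monthly_drug_cost_pfs, "cost >= 0")
        if t.second_line_link is not None:
            chk(t.second_line_link in params.second_line,
                f"{pre}.second_line_link", t.second_line_link,
                "links to a defined second-line profile")

    # second line
    for name, sl in params.second_line.items():
        pre = f"second_line.{name}"
        chk(0 <= sl.share_active_treatment <= 1, f"{pre}.share_active_treatment",
            sl.share_active_treatment, "fraction in [0, 1]")
        chk(sl.median_pfs_2l > 0, f"{pre}.median_pfs_2l", sl.median_pfs_2l, "> 0")

    # allocations
    for aname, table in params.allocations.items():
        for group, arms in table.shares.items():
            tot = sum(arms.values())
            chk(abs(tot - 1.0) <= _ALLOC_TOL,
                f"allocations.{aname}.{group.value}", tot,
                "treatment shares within a molecular group sum to 1 (+-0.001)")
            for tr in arms:
                chk(tr in params.treatments,
                    f"allocations.{aname}.{group.value}.{tr}", tr,
                    "references a defined treatment")
    chk(params.allocation_variant in params.allocations,
        "allocation_variant", params.allocation_variant,
        "selects a defined allocation table")

    # utilities
    u = params.utilities
    for f in ("u_pfs", "u_pd_active", "u_pd_bsc"):
        chk(0 <= getattr(u, f) <= 1, f"utilities.{f}", getattr(u, f),
            "utility in [0, 1]")
    chk(u.u_pd_active <= u.u_pfs, "utilities.u_pd_active", u.u_pd_active,
        "u_pd_active <= u_pfs")

    # economics
    e = params.economics
    chk(e.horizon_years > 0, "economics.horizon_years", e.horizon_years, "> 0")
    chk(e.cycle_length_months > 0, "economics.cycle_length_months",
        e.cycle_length_months, "> 0")
    chk(e.discount_rate_costs >= 0, "economics.discount_rate_costs",
        e.discount_rate_costs, ">= 0")
    chk(e.discount_rate_effects >= 0, "economics.discount_rate_effects",
        e.discount_rate_effects, ">= 0")

    # FP adjustment
    fp = params.fp_adjustment
    chk(fp.median_pfs_fp > 0, "fp_adjustment.median_pfs_fp",
        fp.median_pfs_fp, "> 0")
    chk(fp.median_os_fp > 0, "fp_adjustment.median_os_fp",
        fp.median_os_fp, "> 0")
    if fp.stopping_rule_month is not None:
        chk(fp.stopping_rule_month > 0, "fp_adjustment.stopping_rule_month",
            fp.stopping_rule_month, "> 0 when present")

    # no-testing mix
    if params.no_testing_mix:
        tot = sum(params.no_testing_mix.values())
        chk(abs(tot - 1.0) <= _ALLOC_TOL, "no_testing_mix", tot,
            "shares sum to 1")
        for tr in params.no_testing_mix:
            chk(tr in params.treatments, f"no_testing_mix.{tr}", tr,
                "references a defined treatment")
    else:
        v.append(Violation("no_testing_mix", {}, "must not be empty"))

    if params.include_second_line:
        missing = [n for n, t in params.treatments.items()
                   if t.second_line_link is None]
        chk(not missing, "treatments", missing,
            "every treatment needs a second-line link when "
            "include_second_line is true")

    return v


# ---------------------------------------------------------------------------
# provenance helpers


def iter_numeric_leaves(params: ModelParameters):
    """Yield ``(dotted_path, value)`` for every numeric scalar in the set.

    Used by the provenance-completeness check: each leaf must have a tag in
    ``params.provenance``.
    """

    def walk(obj, path: str):
        if isinstance(obj, BaseModel):
            for fname in type(obj).model_fields:
                if path == "" and fname in ("provenance", "metadata", "psa"):
                    continue
                yield from walk(getattr(obj, fname), f"{path}.{fname}" if path else fname)
        elif isinstance(obj, dict):
            for k, val in obj.items():
                key = k.value if isinstance(k, enum.Enum) else str(k)
                yield from walk(val, f"{path}.{key}")
        elif isinstance(obj, list):
            for item in obj:
                if isinstance(item, TestStrategy):
                    yield from walk(item, f"{path}.{item.name.value}")
                else:  # pragma: no cover - no other list payloads today
                    yield from walk(item, f"{path}[]")
        elif isinstance(obj, bool) or obj is None or isinstance(obj, (str, enum.Enum)):
            return
        elif isinstance(obj, (int, float)):
            yield path, obj

    yield from walk(params, "")


# ---------------------------------------------------------------------------
# serialisation (single YAML document)


class ParameterFileError(ValueError):
    """Raised when a parameter file fails schema or invariant validation."""


def _to_plain(params: ModelParameters) -> dict:
    return params.model_dump(mode="json")


def write_parameters(params: ModelParameters, path: Union[str, Path]) -> None:
    """Write the full parameter set to one YAML file."""
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(_to_plain(params), fh, sort_keys=False)


def load_parameters(path: Union[str, Path]) -> ModelParameters:
    """Load and fully validate a parameter file.

    Raises :class:`ParameterFileError` naming the offending field for both
    schema-level problems (e.g. a sensitivity of 1.2) and cross-field
    invariant violations (e.g. strategy shares not summing to 1).
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    try:
        params = ModelParameters.model_validate(raw)
    except Exception as exc:
        raise ParameterFileError(f"{path}: {exc}") from exc
    violations = validate(params)
    if violations:
        lines = "; ".join(str(x) for x in violations)
        raise ParameterFileError(f"{path}: invalid parameter set: {lines}")
    return params
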