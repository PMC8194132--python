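"""The published parameter set for the Spanish ALK-testing analysis.

:func:`paper_fixture` encodes every value printed in the source tables
(epidemiology cascade, strategy mix and accuracy, biomarker positivity,
test and biopsy costs, treatment allocation, utilities, discounting, the
false-positive survival adjustment) verbatim.  First-line survival medians,
monthly drug costs and the second-line table were sourced by the original
analysis from trials and national price lists without being printed; they
are shipped as clearly labelled placeholders in ``data/external_fixture.yaml``
and tagged ``external-fixture`` so users can substitute real values.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .params import (
    AllocationTable,
    BiomarkerPanel,
    EconomicSettings,
    EpidemiologyInputs,
    FalsePositiveAdjustment,
    ModelParameters,
    MolecularGroup,
    Provenance,
    PSASettings,
    RebiopsyPolicy,
    SecondLineProfile,
    StrategyName,
    TestStrategy,
    TreatmentProfile,
    UtilitySet,
    iter_numeric_leaves,
)

__all__ = ["paper_fixture", "external_fixture_values"]


def external_fixture_values() -> dict:
    """Load the external-fixture placeholder tables (treatments, 2nd line)."""
    ref = resources.files("alkcea.data") / "external_fixture.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


# fields whose values come from the external-fixture file rather than the
# printed tables; everything else in a treatment profile is printed
_TREATMENT_PAPER_FIELDS = {"admin_unit_cost"}


def _tag_provenance(params: ModelParameters) -> None:
    prov: dict[str, str] = {}
    for path, _ in iter_numeric_leaves(params):
        top = path.split(".", 1)[0]
        if top in ("epidemiology", "strategies", "biomarkers", "rebiopsy",
                   "allocations", "utilities", "economics", "fp_adjustment",
                   "no_testing_mix"):
            prov[path] = Provenance.PAPER.value
        elif top == "treatments":
            leaf = path.rsplit(".", 1)[-1]
            prov[path] = (Provenance.PAPER.value
                          if leaf in _TREATMENT_PAPER_FIELDS
                          else Provenance.EXTERNAL_FIXTURE.value)
        elif top == "second_line":
            prov[path] = Provenance.EXTERNAL_FIXTURE.value
        else:
            prov[path] = Provenance.USER.value
    params.provenance.update(prov)


def paper_fixture() -> ModelParameters:
    """Build the full published parameter set (base-case configuration)."""
    ext = external_fixture_values()

    treatments = {
        name: TreatmentProfile(name=name, **spec)
        for name, spec in ext["treatments"].items()
    }
    second_line = {
        name: SecondLineProfile(name=name, **spec)
        for name, spec in ext["second_line"].items()
    }

    allocations = {
        "base_case": AllocationTable(
            name="base_case",
            shares={
                MolecularGroup.ALK: {"alectinib": 0.8938,
                                     "crizotinib_alk": 0.1063},
                MolecularGroup.EGFR: {"erlotinib": 0.15, "gefitinib": 0.30,
                                      "afatinib": 0.15, "osimertinib": 0.40},
                MolecularGroup.ROS1: {"crizotinib_ros1": 1.0},
                MolecularGroup.WT_TPS_HIGH: {"pembrolizumab": 1.0},
                MolecularGroup.WT_TPS_LOW: {"cis_pem": 0.30,
                                            "carb_pac_bev": 0.10,
                                            "cis_pem_pembro": 0.60},
            },
        ),
        "alternative": AllocationTable(
            name="alternative",
            shares={
                MolecularGroup.ALK: {"alectinib": 0.80,
                                     "crizotinib_alk": 0.20},
                MolecularGroup.EGFR: {"gefitinib": 0.30, "afatinib": 0.05,
                                      "osimertinib": 0.65},
                MolecularGroup.ROS1: {"crizotinib_ros1": 1.0},
                MolecularGroup.WT_TPS_HIGH: {"pembrolizumab": 1.0},
                MolecularGroup.WT_TPS_LOW: {"cis_pem": 0.40,
                                            "carb_pac_bev": 0.05,
                                            "cis_pem_pembro": 0.55},
            },
        ),
    }

    params = ModelParameters(
        epidemiology=EpidemiologyInputs(
            lung_cancer_cases=28475,
            nsclc_share=0.85,
            stage_iv_share=0.545,
            nonsquamous_share=0.669,
            squamous_share=0.331,
            squamous_never_smoker_share=0.16,
            testing_rate=0.801,
        ),
        strategies=[
            TestStrategy(name=StrategyName.IHC, share_of_patients=0.372,
                         sensitivity=0.968, specificity=0.979,
                         invalid_rate=0.026, unit_cost=60.28),
            TestStrategy(name=StrategyName.FISH, share_of_patients=0.116,
                         sensitivity=0.909, specificity=0.998,
                         invalid_rate=0.026, unit_cost=111.36),
            TestStrategy(name=StrategyName.REFLEX, share_of_patients=0.465,
                         invalid_rate=0.026),
            TestStrategy(name=StrategyName.NGS, share_of_patients=0.047,
                         sensitivity=1.0, specificity=1.0,
                         invalid_rate=0.034, unit_cost=475.0),
        ],
        biomarkers=BiomarkerPanel(
            alk_prevalence=0.034,
            egfr_prevalence=0.136,
            ros1_prevalence=0.02,
            pdl1_high_prevalence=0.33,
            egfr_test_cost=165.0,
            ros1_test_cost=100.0,
            pdl1_test_cost=130.0,
        ),
        rebiopsy=RebiopsyPolicy(rebiopsy_probability=0.771,
                                biopsy_cost=411.22, max_repeats=1),
        treatments=treatments,
        second_line=second_line,
        allocations=allocations,
        allocation_variant="base_case",
        utilities=UtilitySet(u_pfs=0.814, u_pd_active=0.725, u_pd_bsc=0.470),
        economics=EconomicSettings(
            discount_rate_costs=0.03,
            discount_rate_effects=0.03,
            horizon_years=20.0,
            cycle_length_months=1.0,
            body_surface_area=1.81,
            body_weight=72.885,
            vial_sharing=True,
        ),
        fp_adjustment=FalsePositiveAdjustment(
            median_pfs_fp=2.0, stopping_rule_month=6.0, median_os_fp=18.0),
        psa=PSASettings(),
        diagnosis_mode="parallel",
        include_second_line=True,
        no_testing_mix={"cis_pem": 0.30, "carb_pac_bev": 0.10,
                        "cis_pem_pembro": 0.60},
        metadata={
            "country": "Spain",
            "price_year": "2019/2020 (source ambiguous)",
            "perspective": "national health system, direct costs",
        },
    )
    _tag_provenance(params)
    return params
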