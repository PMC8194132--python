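"""Target-population cascade: from national lung-cancer incidence to the
number of patients actually tested for ALK rearrangement.

All arithmetic is carried unrounded; half-up rounding to whole patients is
applied only to the display counts.  This matters: the candidate row equals
the unrounded non-squamous plus never-smoker-squamous counts (9523.41 ->
9523), not the sum of the two already-rounded rows (8825 + 699 = 9524).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

from .params import EpidemiologyInputs

__all__ = ["PopulationCascade", "compute_cascade", "scale_scenario", "round_half_up"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going away from zero."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PopulationCascade:
    """Unrounded per-step counts; ``display`` renders the printed table."""

    lung_cancer_cases: float
    nsclc: float
    stage_iv: float
    nonsquamous: float
    squamous: float
    squamous_never_smoker: float
    candidates: float
    tested: float
    steps: tuple[str, ...] = field(default=(
        "lung_cancer_cases", "nsclc", "stage_iv", "nonsquamous", "squamous",
        "squamous_never_smoker", "candidates", "tested"), repr=False)

    def display(self) -> dict[str, int]:
        return {s: round_half_up(getattr(self, s)) for s in self.steps}


def compute_cascade(epi: EpidemiologyInputs) -> PopulationCascade:
    """Apply the cascade fractions to the incident population.

    Candidates for ALK testing are all stage-IV non-squamous patients plus
    the never-smoker fraction of stage-IV squamous patients; the tested
    population applies the national testing rate on top.
    """
    cases = float(epi.lung_cancer_cases)
    nsclc = cases * epi.nsclc_share
    stage_iv = nsclc * epi.stage_iv_share
    nonsq = stage_iv * epi.nonsquamous_share
    sq = stage_iv * epi.squamous_share
    sq_ns = sq * epi.squamous_never_smoker_share
    candidates = nonsq + sq_ns
    tested = candidates * epi.testing_rate
    return PopulationCascade(
        lung_cancer_cases=cases, nsclc=nsclc, stage_iv=stage_iv,
        nonsquamous=nonsq, squamous=sq, squamous_never_smoker=sq_ns,
        candidates=candidates, tested=tested)


def scale_scenario(cascade: PopulationCascade, subset_share: float) -> PopulationCascade:
    """Restrict the tested population to a subset (e.g. adenocarcinoma only).

    Only the tested count is scaled; upstream steps describe the national
    epidemiology and are left untouched.  Because both compared scenarios
    run on the same population basis, scaling leaves ICER/ICUR unchanged.
    """
    if not (0 < subset_share <= 1):
        raise ValueError(f"subset_share must be in (0, 1], got {subset_share}")
    return replace(cascade, tested=cascade.tested * subset_share)
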