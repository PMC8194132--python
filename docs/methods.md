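# Methods

## Model structure and assumptions

The package couples a diagnostic decision tree to per-treatment
three-state partitioned-survival cohort models and compares a national
ALK-testing scenario against a hypothetical no-testing scenario for
advanced NSCLC in Spain. The unit of analysis is one annual incident
cohort of tested patients; both compared scenarios always run on the same
population basis, so population size scales every total linearly and
leaves the incremental ratios untouched (asserted by test).

### Population cascade

Cascade fractions (NSCLC share 85%, stage IV 54.5%, non-squamous 66.9%,
never-smoker squamous 16%, testing rate 80.1%) are applied to unrounded
intermediates; display counts are rounded half-up only at presentation.
This is required to reproduce the published candidate count: 8824.81 +
698.60 = 9523.41 → 9523, whereas the pre-rounded rows would give 9524.

### Decision tree

Four strategies (IHC 37.2%, FISH 11.6%, reflex 46.5%, NGS 4.7%) each
contribute their classification probabilities on their resolved fraction.
Choices the source leaves open, and how they are fixed here:

* **Reflex composition.** Positives are confirmed serially, so
  Se = Se_IHC·Se_FISH, Sp = 1 − (1−Sp_IHC)(1−Sp_FISH), and expected cost
  c_IHC + P(IHC+)·c_FISH. Validated against explicit enumeration over the
  truth × IHC-result × FISH-result outcomes.
* **Invalid results.** One rebiopsy loop: invalids (2.6% for IHC/FISH/
  reflex at the IHC stage, 3.4% for NGS) rebiopsy with probability 77.1%
  and the repeat assay is assumed interpretable; the remainder start
  chemotherapy untested. Every patient is billed one expected assay;
  rebiopsied patients are billed the biopsy (€411.22) and a second assay.
  `max_repeats` is configurable but defaults to the single loop.
* **Companion-test costing (parallel mode, the base case).** EGFR (€165)
  and ROS1 (€100) are billed to ALK-result-negative patients, PD-L1
  (€130) to every patient with an interpretable result. Under this
  convention the fixture yields €481.0 per tested patient, within 1.6% of
  the €473.7 implied by the published totals (3,613,701 / 7,628).
* **Sequential mode** is a billing convention only (classification and
  outcomes unchanged, matching the published scenario where only the
  testing-scenario cost moved): EGFR first for everyone, ALK assay and
  its invalid/rebiopsy costs only for the (1 − 13.6%) EGFR-negatives,
  ROS1 for EGFR-negatives with an ALK-negative result.
* **Downstream cascade.** Printed marginal positivity rates are
  renormalised among ALK-negatives under mutual exclusivity of drivers:
  P(EGFR+|ALK−) = 0.136/0.966, then ROS1 2%/(1−0.034−0.136) among
  EGFR-negatives, then TPS ≥ 50% at 33% among panel-negatives. False
  negatives (truly ALK+) have EGFR/ROS1 forced negative; PD-L1 is still
  informative for them.
* **Allocation renormalisation.** Treatment shares are stored verbatim
  (the printed ALK column sums to 100.01%) and renormalised within each
  molecular group when cohort fractions are built, so arm fractions sum
  to exactly 1.
* **Truth flags.** Besides TP/FP, truly ALK-positive patients on
  non-targeted therapy (false negatives, untested, and the no-testing
  cohort's 3.4%) carry an `ALK_MISSED` flag: they use non-targeted curves
  unmodified (the harm of a missed ALK is the lost targeted-therapy
  benefit, nothing more) but remain identifiable for reporting.

### Survival and the cohort engine

Exponential extrapolation from medians (λ = ln 2/median) in monthly
cycles over 20 years (240 cycles). Occupancy: PFS(t) = min(S_pfs, S_os),
Death = 1 − S_os, PD the remainder; the PFS rate is clamped to at least
the OS rate so PD never goes negative. No background general-population
mortality is added.

* **Dependence structure.** Progression and death times are coupled
  comonotonically (one latent uniform drives both marginals). This is the
  unique coupling whose joint survivor function equals the pointwise
  minimum used for occupancy, so the cohort engine and the
  individual-patient microsimulation estimate the same quantity; the
  microsimulation draws from that same coupling. Under it, progression
  strictly precedes death whenever the PFS rate exceeds the OS rate, so
  every PFS exit is a progression — the per-cycle entering-PD fraction is
  the PFS decrement (with the stopping-rule jump included); with equal
  rates nobody progresses.
* **Discounting and integration.** Annual rates convert to continuous
  monthly rates ρ = ln(1 + r)/12, making the cycle-boundary factor
  exactly (1 + r)^(−t/12). LY/QALY/cost are trapezoidal integrals of the
  discounted occupancy; for an exponential arm this lands within ~0.02%
  of the closed form (1 − e^{−(λ+ρ)T})/(λ+ρ), comfortably inside the
  0.5% oracle tolerance. Effects and costs use separate discount rates.
* **Costs.** Monthly drug cost accrues over the whole PFS occupancy
  (treatment to progression, no duration cap or dose reductions; vial
  sharing assumed, so no wastage). IV administration (€211/visit) accrues
  likewise. Dose-dependent IV drugs expose `bsa_scaled_fraction` /
  `weight_scaled_fraction`: that share of the monthly cost scales
  linearly with BSA (reference 1.81 m²) and weight (reference 72.885 kg),
  giving body size its tornado channel.
* **Second line** is a one-off cost at progression: active-treatment
  share × monthly (drug + administration) cost × expected duration
  (exponential mean, median/ln 2), charged to each cycle's entering-PD
  fraction at the cycle midpoint. PD utility is blended by the linked
  second line's active share: u_PD = s·0.725 + (1−s)·0.470.
* **False positives** keep the targeted arm's cost structure on PFS
  median 2 months (stopping rule month 6) and OS median 18 months,
  irrespective of the arm they would otherwise occupy.

### Sensitivity analyses

* **Scenario registry**: horizons 10/5/3 years, adenocarcinoma-only
  (subset share = non-squamous / candidates, computed from the inputs),
  a three-year testing-rate ramp (80.1/85/90%, modelled as three
  identical annual cohorts each run over the full horizon and summed),
  sequential diagnosis, invalid rates 1% (IHC/FISH) and 0% (all),
  alternative allocation, FP response variants, and no second line.
  Scenario runs operate on deep copies; purity is asserted.
* **One-way**: default ±10% per variable (the source states 10% or 20%
  per variable without enumerating which; the per-variable delta is
  overridable). Default variable list: body size, discount rates, EGFR
  prevalence, utilities, test/biopsy unit costs, second-line costs.
* **Bivariate**: additive percentage-point deltas applied simultaneously
  to IHC and FISH sensitivity (rows) and specificity (columns), clamped
  to [0, 1]; cells report total QALY gain.
* **PSA**: each draw resamples every uncertain parameter, moment-matched
  to its mean — beta for utilities (α = m(k), β = (1−m)k with
  k = m(1−m)/v − 1), gamma for unit costs (shape m²/v, scale v/m), normal
  for body size, medians, positivity rates, invalid rates and rebiopsy
  probability, truncated to [0, 1] for probabilities and to positive
  values for medians. Dispersions are not published; the default is
  SE = 10% of the mean, per-parameter overridable, zero dispersion
  degenerating exactly to the deterministic run. Sensitivities/
  specificities are excluded from the PSA (they are the bivariate
  analysis's subject). A single seeded generator with a fixed sampling
  order makes runs bit-reproducible.

## Synthetic data

`generate_parameter_set` draws complete, internally consistent parameter
sets (Dirichlet shares, ordered utilities, PFS ≤ OS by construction) for
property tests; it emulates the *structure* of the real inputs, not
Spanish epidemiology, so passing property tests demonstrates algebraic
correctness (enumerator equality, partition identities, oracle agreement)
— not that any particular national estimate is right. The microsimulation
is the stochastic oracle for the cohort engine; its per-patient outcomes
use exact event times and closed-form discount integrals.

## Problem sizes and numerics

Default runs use 240 monthly cycles per arm, 1000 PSA draws and 100,000
microsimulation patients per oracle arm — the published analysis's own
cycle count and draw count, and an oracle size giving ~0.3% standard
errors. Ties and degenerate inputs: equal PFS/OS rates produce zero PD
occupancy and zero progressions; stopping rules empty PFS by forced
progression of survivors; zero-share strategies are skipped; undefined
ICERs (zero effect increment) and dominance quadrants are flagged rather
than reported as signed ratios.

## Known limitations

Exponential extrapolation from medians is the source analysis's own
simplification (no patient-level data); no other distributions are
offered. No turnaround-time effects, adverse events, multi-biomarker NGS
benefit or liquid biopsy. Monthly drug costs are inputs — no price-list
arithmetic or statutory deductions. The shipped treatment medians, drug
costs and second-line table are labelled placeholders of realistic
magnitude; every result that depends on them (base-case totals, ICUR
magnitude) moves with the values users substitute, while the cascade,
decision-tree quantities and all structural properties depend only on
published inputs.
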