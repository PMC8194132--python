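# alkcea

A cost-effectiveness model of ALK-rearrangement testing in advanced
non-small-cell lung cancer (NSCLC), built for health-economics analysts
who want a tested, scriptable re-implementation of the Spanish
testing-vs-no-testing analysis: a diagnostic decision tree feeding
per-treatment partitioned-survival Markov models, with the full
deterministic and probabilistic sensitivity-analysis machinery.

## The model

**Population.** An annual incident cohort is cascaded from national
lung-cancer cases through NSCLC share, stage IV, histology and the
never-smoker squamous fraction to the ALK-testing candidates, then
multiplied by the national testing rate. Arithmetic is carried unrounded;
only display counts are rounded half-up.

**Decision tree.** Each tested patient passes through one of four ALK
strategies — IHC, FISH, reflex (IHC with FISH confirmation of positives),
NGS — with national shares *w*. An invalid result (rate *i*) triggers a
rebiopsy with probability 77.1%; otherwise chemotherapy starts with no
molecular result. Interpretable results classify by the standard test
algebra with ALK prevalence *p*:

    TP = p·Se    FP = (1−p)(1−Sp)    TN = (1−p)·Sp    FN = p(1−Se)

Reflex testing composes serially: Se = Se_IHC·Se_FISH,
Sp = 1 − (1−Sp_IHC)(1−Sp_FISH). ALK-negative patients cascade through the
companion panel (EGFR → ROS1 → PD-L1 TPS) with marginal positivity rates
renormalised among ALK-negatives; false negatives have EGFR/ROS1 forced
negative. Each molecular group maps to its first-line treatment mix.

**Markov models.** One three-state partitioned-survival model per
treatment (PFS, progressed disease, death; monthly cycles; 20-year
horizon). PFS and OS are exponential, rate λ = ln 2 / median; occupancy is
read off the curves: PFS(t) = min(S_pfs, S_os), Death(t) = 1 − S_os.
False positives on ALK-targeted therapy get PFS median 2 months (all
progressed by month 6) and OS median 18 months. Drug + administration
costs accrue in PFS; second line enters as a one-off cost at progression;
utilities 0.814 (PFS), 0.725 / 0.470 (PD with/without active treatment);
costs and effects discounted at 3%/year.

**Comparison.** The testing scenario is compared with a hypothetical
no-testing scenario (whole cohort on the non-targeted mix) through
ICER (€/LY gained) and ICUR (€/QALY gained), plus scenario analyses,
one-way tornado, a bivariate IHC/FISH accuracy grid and a 1000-draw
second-order Monte-Carlo PSA (beta / normal / gamma families).

Survival medians, monthly drug costs and the second-line table are not
printed in the source publication; the package ships clearly labelled
placeholder values in `src/alkcea/data/external_fixture.yaml` (tagged
`external-fixture` in the parameter provenance) which users should replace
for a production analysis.

## Worked example

```python
from alkcea import paper_fixture, compute_cascade, run_base_case

params = paper_fixture()          # every printed value, verbatim
print(compute_cascade(params.epidemiology).display()["tested"])
r = run_base_case(params)
print(f"ICUR EUR {r.icur_per_qaly_rounded:,}/QALY over {r.d_qaly:,.1f} QALYs gained")
```

prints

```
7628
ICUR EUR 34,032/QALY over 3,439.5 QALYs gained
```

7628 is the annual Spanish cohort tested for ALK. With the shipped
placeholder treatment inputs, testing gains ~3,440 discounted QALYs over
20 years at ~€117 M incremental cost, i.e. ~€34,032 per QALY gained — the
mechanics of the published analysis; the absolute totals track whatever
treatment inputs you supply. The narrative scripts in `examples/` walk
each capability (cascade, split, base case, deterministic SA, PSA), and
the `alkcea` CLI exposes the same steps
(`alkcea run`, `cascade`, `split`, `trace`, `scenarios`, `tornado`,
`bivariate`, `psa`, `synth`, `fixture`, `microsim`).

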