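"""Decision tree: strategy mix -> TP/FP/TN/FN split and testing cost.

Mixes the four ALK assay strategies (IHC, FISH, reflex, NGS) with their
accuracy, invalid rates and the rebiopsy policy, then cross-checks the
closed-form mixture against the brute-force event-tree enumerator.
"""

from alkcea import (allocate_treatments, build_split, enumerate_event_tree,
                    paper_fixture)

params = paper_fixture()
split = build_split(params)

print("Cohort fractions (per tested patient):")
for name in ("tp", "fp", "tn", "fn", "untested_chemo"):
    print(f"  {name:<16}{getattr(split, name):>10.6f}")
print(f"  expected testing cost  EUR {split.expected_testing_cost:7.2f}")
print(f"  expected biopsy  cost  EUR {split.expected_biopsy_cost:7.2f}")

enum = enumerate_event_tree(params)
print(f"\nEnumerator agreement on TP fraction: |diff| = {abs(enum.tp - split.tp):.2e}")

dist = allocate_treatments(split, params.biomarkers, params.allocation(),
                           params.no_testing_mix)
print("\nTreatment-arm distribution (top 6 by cohort fraction):")
for e in sorted(dist.entries, key=lambda e: -e.fraction)[:6]:
    print(f"  {e.treatment:<16}{e.truth.value:<12}{e.fraction:.4f}")
print("A TP fraction of ~3.1% reaches ALK-targeted therapy; false positives"
      " (~0.8%) receive it without benefit.")
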