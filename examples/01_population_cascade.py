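"""From national lung-cancer incidence to the ALK-tested population.

Builds the published epidemiology inputs and walks the cascade: NSCLC
share, stage IV, histology, the never-smoker squamous fraction, and the
national testing rate.  Arithmetic is carried unrounded; only the display
counts are rounded (half-up), which is why the candidate row is 9523 and
not 8825 + 699 = 9524.
"""

from alkcea import compute_cascade, paper_fixture

params = paper_fixture()
cascade = compute_cascade(params.epidemiology)

print(f"{'step':<28}{'unrounded':>14}{'display':>10}")
for step, count in cascade.display().items():
    print(f"{step:<28}{getattr(cascade, step):>14.2f}{count:>10d}")

print("\nThe final row is the annual cohort entering the diagnostic model:"
      f" {cascade.display()['tested']} patients tested for ALK rearrangement.")
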