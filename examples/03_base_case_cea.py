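"""Base case: testing vs no-testing over a 20-year horizon.

Runs the full pipeline and prints total discounted costs, life-years and
QALYs for both scenarios plus the incremental ratios.  Treatment medians
and monthly drug costs are the shipped external-fixture placeholders, so
the totals illustrate the model mechanics rather than reproduce the
published totals (which used unprinted trial and price-list inputs).
"""

from alkcea import paper_fixture, run_base_case

r = run_base_case(paper_fixture())

print(f"{'':<22}{'testing':>16}{'no-testing':>16}")
print(f"{'testing cost (EUR)':<22}{r.tested.testing_cost:>16,.0f}{0:>16,.0f}")
print(f"{'treatment cost (EUR)':<22}{r.tested.treatment_cost:>16,.0f}"
      f"{r.untested.treatment_cost:>16,.0f}")
print(f"{'life-years':<22}{r.tested.ly:>16,.1f}{r.untested.ly:>16,.1f}")
print(f"{'QALYs':<22}{r.tested.qaly:>16,.1f}{r.untested.qaly:>16,.1f}")
print(f"\nincremental cost   EUR {r.d_cost:,.0f}")
print(f"LY gained          {r.d_ly:,.1f}")
print(f"QALYs gained       {r.d_qaly:,.1f}")
print(f"ICER               EUR {r.icer_per_ly_rounded:,}/LY gained")
print(f"ICUR               EUR {r.icur_per_qaly_rounded:,}/QALY gained")
print("\nTesting buys several thousand discounted QALYs for the national"
      " cohort; the ICUR is the price paid per QALY gained.")
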