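"""One-way, two-way and probabilistic sensitivity analyses.

Prints the tornado head (which parameters move the ICER the most when
varied +/-20%), the two-way cost-effectiveness boundary in the
intervention-arm PFS utility, and a 2,000-draw PSA with the probability
of cost-effectiveness at $150,000/QALY and the break-even willingness-
to-pay at 50% probability.
"""

import numpy as np

from oncocea import builtin_inputs, ceac, one_way, run_psa, two_way, wtp_at_probability

inputs = builtin_inputs("overall")

print("tornado (top 5 of ~28 parameters, ICER span in $/QALY):")
for e in one_way(inputs)[:5]:
    print(f"  {e.parameter:48s} span {e.span:10,.0f} "
          f"[{e.icer_at_low:,.0f} .. {e.icer_at_high:,.0f}]")

grid = np.round(np.linspace(0.70, 1.00, 31), 3)
cells = two_way(inputs, "intervention.utility_pfs", grid,
                "comparator.utility_pfs", [0.84], wtp=150_000.0)
frontier = cells[cells.cost_effective]["intervention.utility_pfs"].min()
print(f"\ntwo-way: combination cost-effective once its PFS utility exceeds "
      f"~{frontier:.3f} (comparator utility at baseline 0.84)")

draws = run_psa(inputs, n_iterations=2_000, seed=7)
curve = ceac(draws)
p150 = next(p for p in curve if p.wtp == 150_000).probability_cost_effective
print(f"\nPSA (n=2,000): P(cost-effective at $150,000/QALY) = {p150:.1%}")
print(f"break-even WTP at 50% probability: ${wtp_at_probability(curve, 0.5):,.0f}/QALY")
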