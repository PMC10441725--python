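"""Base-case cost-effectiveness for one molecular subgroup.

Builds the bundled overall-population inputs, runs both strategy arms
through the 15-year / 3-week-cycle cohort model and prints the per-arm
discounted totals plus the incremental comparison.  The ICER is the extra
spend per additional quality-adjusted life-year bought by adding
maintenance olaparib to bevacizumab; it is judged against a $150,000/QALY
willingness-to-pay threshold.
"""

from oncocea import builtin_inputs, net_monetary_benefit, outcome_table, run_base_case

inputs = builtin_inputs("overall")
print(outcome_table(inputs).to_string(index=False, float_format=lambda v: f"{v:,.2f}"))

inter, comp, ce = run_base_case(inputs)
wtp = inputs.econ.wtp_per_qaly
nmb = net_monetary_benefit(ce.delta_cost, ce.delta_qaly, wtp)
print(f"\nincremental cost  ${ce.delta_cost:,.0f}")
print(f"incremental QALYs {ce.delta_qaly:.3f}  (LYs {ce.delta_ly:.3f})")
print(f"ICER              ${ce.icer_per_qaly:,.0f}/QALY  ({ce.status})")
print(f"NMB at ${wtp:,.0f}/QALY: ${nmb:,.0f} "
      f"({'cost-effective' if nmb >= 0 else 'not cost-effective'})")

print("\nintervention cost breakdown (discounted USD):")
for name, value in sorted(inter.cost_components.items(), key=lambda kv: -kv[1]):
    print(f"  {name:18s} {value:12,.0f}")
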