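# oncocea

Cost-effectiveness modelling of **maintenance olaparib + bevacizumab versus
bevacizumab alone** in newly diagnosed advanced ovarian cancer (AOC), from a
US payer perspective, for four molecular subgroups: all comers, BRCA-mutated,
HRD-positive, and HRD-positive/BRCA-wild-type.

The package is a library for health-economics researchers who want to
rebuild, probe or extend this evaluation: every input is a typed, validated
parameter; every stage — survival fitting, cohort trace, accrual,
incremental comparison, sensitivity analysis — is an importable function.
A thin `oncocea` command wraps the common runs.

## The model

A cohort state-transition model over three mutually exclusive states —
progression-free (PFS), progressed disease (PD), dead — on a 3-week cycle
over a 15-year horizon. State membership is driven by Weibull laws
(time in months, survivor function `S(t) = exp(-scale * t^shape)`) fitted
to the PAOLA-1 trial's progression-free and overall survival curves, one
pair per arm and subgroup. Two clock conventions are implemented:

* **`progression`** (default): the PFS curve carries every exit from the
  PFS state; patients who progress then die according to the OS law with
  its clock restarted at progression entry. PD occupancy is the
  convolution of the progression inflow with the OS survivor function.
* **`model_start`**: classic partitioned survival — PFS membership is
  `S_PFS(t)`, death is `1 - S_OS(t)`, PD the clamped difference.

Per cycle, each arm accrues discounted (3%/year, continuous convention
`(1+r)^(-t/12)`) quality-adjusted survival (utilities 0.84 PFS / 0.79 PD,
one-off adverse-event disutilities) and costs: maintenance drugs to their
protocol caps (olaparib 2 years, weight-dosed bevacizumab 15 months),
administration, laboratory and imaging follow-up, one-off BRCA/HRD testing,
adverse-event management, second-line carboplatin + paclitaxel for the
treated fraction of progressors, best supportive care for the rest, and
terminal care at death. The headline statistic is the incremental
cost-effectiveness ratio

```
ICER = (C_olaparib+bev - C_bev) / (E_olaparib+bev - E_bev)   [$ per QALY or LY]
```

judged against a $150,000/QALY willingness-to-pay (WTP) threshold, with
net monetary benefit `NMB = WTP * dQALY - dCost`. One-way (±20% tornado),
two-way (utility grids) and probabilistic (10,000-draw Monte Carlo with
beta/gamma/normal/uniform parameter distributions, CEAC) sensitivity
analyses sit on top. `docs/methods.md` documents every convention,
including where the defaults were reverse-engineered from the published
base case and why parts of that base case cannot be reproduced from its
own printed survival parameters.

## Worked example

```python
from oncocea import builtin_inputs, run_base_case

inputs = builtin_inputs("overall")           # Table-derived fixture
inter, comp, ce = run_base_case(inputs)
print(f"{comp.total_cost:,.0f} {inter.total_cost:,.0f} "
      f"{ce.delta_qaly:.3f} {ce.icer_per_qaly:,.0f}")
```

prints

```
317,151 448,939 0.983 134,012
```

meaning: over 15 years the bevacizumab strategy costs ≈ $317k discounted
and the combination ≈ $449k; adding olaparib buys 0.983 extra QALYs at
$134,012 per QALY — just under the $150,000/QALY threshold, so the
combination is (marginally) cost-effective for the overall population
under these inputs. The `examples/` scripts walk through the base case
and cost breakdown (`base_case.py`), survival fitting with AIC/BIC
selection on synthetic right-censored data (`survival_fit.py`) and the
tornado / two-way / PSA analyses (`sensitivity_analyses.py`).

Command-line equivalents:

```bash
oncocea base-case --subgroup brca_mut --out results/brca
oncocea tornado   --subgroup overall  --out results/tornado
oncocea psa       --subgroup overall --n 10000 --seed 1 --out results/psa
oncocea validate  src/oncocea/fixtures/hrd_pos.yaml
```

Parameter files are plain YAML mirroring the input types field for field
(see `src/oncocea/fixtures/*.yaml` for the canonical schema); `validate`
reports invariant violations and suspicious-value warnings — e.g. the two
HRD fixtures carry a printed PFS shape equal to its scale, an almost
certainly corrupted value that is flagged on every HRD run.

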