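# Methods

## Decision problem and model structure

The package evaluates first-line maintenance olaparib + bevacizumab against
bevacizumab alone in advanced ovarian cancer from a US payer perspective.
A cohort of identical patients (70 kg, 1.84 m² reference profile) moves
through three mutually exclusive states — progression-free (PFS),
progressed disease (PD), dead — in 3-week cycles over a 15-year horizon
(262 grid points; a month is fixed at 30.4375 days). State membership is
driven entirely by two fitted Weibull laws per arm (PFS and OS, time in
months, `S(t) = exp(-scale * t^shape)`), carried in bundled fixtures for
four molecular subgroups.

Two conventions for turning the two curves into state occupancy are
implemented and selectable via `ModelSettings.os_clock`:

* **`model_start`** — partitioned survival: `pfs_k = S_PFS(t_k)` (clamped
  at `S_OS`), `dead_k = 1 - S_OS(t_k)`, PD the difference. This treats the
  fitted OS curve as all-cause survival from randomisation, which is the
  textbook reading.
* **`progression`** (default) — death occurs only after progression: the
  progression inflow of each cycle (the PFS decrement) subsequently
  survives according to the OS law with its clock restarted at state
  entry, so PD occupancy is the discrete convolution of inflow with
  `S_OS`. Entrants are indexed to the end of their entry cycle, which is
  optimistic by up to half a cycle of PD time.

**Why the non-textbook default.** The published base case this model
rebuilds is mathematically incompatible with the partitioned reading: the
comparator's printed overall-population OS law (scale 0.0025282, shape
1.427602; median ≈ 51 months) bounds 15-year life expectancy at ≈ 4.94
undiscounted years, yet the published table reports 6.46 *discounted*
life-years for that arm — more than any model reading death off that curve
from model start can produce. Only a clock that restarts at progression
approaches the published effect sizes; it is also a common construction in
decision-tree software when a survival distribution is attached to a state
rather than to the model clock. Both engines satisfy identical structural
invariants (occupancy conservation to 1e-12, monotone death, incident
deaths summing to the final death mass) and both are regression-tested;
only the default differs.

Even under the reset clock the published totals are not fully recoverable;
a structured grid search over every discrete convention in this model
(clock, discounting of effects, supportive-care coverage, second-line
duration, treatment-persistence assumptions) brings the overall-population
comparator cost within ~4% and the BRCA per-life-year ICER within ~1%, but
leaves the published incremental cost (≈ $294k) and intervention QALYs
(7.08) unreachable — the printed incremental cost approximately equals the
*full protocol-cap* drug spend, which no occupancy-weighted costing can
produce. The acceptance checks report whatever the model actually
computes; several deliberately remain outside the published values, and
the test docstrings say so.

## Accrual conventions

Per-cycle quantities use a trapezoidal half-cycle correction by default
(averaging start- and end-of-cycle occupancy, applied to the discounted
integrand); one-off costs are never half-cycle corrected. Discounting is
3%/year for costs and effects, continuous-time `(1+r)^(-t/12)` at each
cycle's accrual time.

Effects: life-years are occupied (PFS + PD) time; QALYs weight the states
by utilities 0.84 / 0.79 (arm-specific overrides supported because the
published one- and two-way analyses vary the PFS utility of each arm
separately), minus a one-off adverse-event decrement
`sum(risk x disutility x cycle-years)` charged at cycle 1.

Costs per arm:

* maintenance drugs on PFS occupancy up to protocol caps — olaparib 35
  cycles (2 years), bevacizumab 22 cycles (15 months), the caps stated in
  calendar time and converted at 21 days/cycle; bevacizumab is dosed at
  15 mg/kg so its price scales with body weight / 70 kg;
* administration charged on intravenous (bevacizumab or chemo) cycles;
* laboratory ($4/cycle; the printed value is ambiguous and read as 4 with
  range 3–5) and imaging ($105/cycle) during PFS only — supportive care is
  taken to subsume routine monitoring after progression;
* germline BRCA ($2,901) + HRD ($4,682) testing once per patient in both
  arms (the underlying trial genotyped everyone; zero the prices to model
  intervention-only testing);
* adverse-event management as a one-off at model entry ($291 / $76);
* second line: the treated fraction of each cycle's progression inflow
  (48.4% / 61.0%) receives carboplatin + paclitaxel (+administration) for
  6 cycles — the standard course length, absent from the source — with
  occupancy capped by the PD state;
* best supportive care ($4,143/cycle) accrues on the **never-second-line
  share** of PD occupancy until death. The source text assigns BSC to "all
  other patients" (those not receiving active second line), and this
  reading reproduces the comparator's published total cost to ~4%,
  whereas extending BSC to the whole PD state overshoots it by ~48%;
  second-line recipients carry no modelled cost after their course;
* terminal care ($85,904) once per incident death, discounted to the death
  cycle.

## Survival module

Five families (exponential, Weibull, log-logistic, log-normal, Gompertz)
share the scale/shape parameterization documented in
`oncocea/survival.py`; the Gompertz shape is restricted positive.
Medians and quantiles are closed-form. Fitting maximises the
right-censored log-likelihood over log-parameters with Nelder–Mead
(fatol 1e-8) from several moment-style starts; AIC/BIC follow the usual
definitions and selection is min-AIC with BIC then parsimony as
tie-breaks (the source does not state which criterion took precedence when
they disagreed). The lifelines fitters serve as an independent likelihood
oracle in the tests, never as the implementation.

## Synthetic patient data

`simulate_ipd` draws event times by inverse-transform from any supported
law and censors by the earlier of an administrative cutoff and exponential
dropout. This emulates the *statistical* structure of trial-figure
reconstruction — right-censored times from a parametric truth — but none
of its systematic artefacts (pixel quantisation, at-risk-table anchoring,
informative censoring), so passing recovery tests demonstrate correctness
of the fitting machinery, not robustness to digitisation error. Defaults
used in tests (n = 5,000, ~20% censoring via a 120-month cutoff plus
0.002/month dropout) give parameter recovery within 10% for the averaged
estimates; the Weibull scale alone has ~5% sampling SD at that n because
it is strongly log-correlated with the shape through the ~51-month median.

## Probabilistic sensitivity analysis

Every parameter with a printed distribution family is sampled per draw
(~27 parameters): beta for probabilities and utilities, gamma for costs,
truncated normal for body metrics, uniform for the discount rate; the
fitted survival parameters stay fixed (no distribution is printed for
them). The source gives ranges but no variances, so beta/gamma are
moment-matched with SE = (high - low)/(2 x 1.96), the range read as a 95%
interval; the PFS-utility upper bound (printed 1.008) is clipped to 1.
The bevacizumab price moves identically in both arms via a joined
parameter path; carboplatin and paclitaxel are sampled as their summed
per-cycle cost. Default 10,000 iterations (2,000 in the test suite for
runtime), CEAC on a $0–300,000 grid in $2,000 steps, break-even WTP by
linear interpolation at probability 0.5.

The published PSA appears to carry substantially more parameter
uncertainty than this 95%-interval reconstruction: with it, the
probability of cost-effectiveness at $150,000/QALY computes to ~73%
(overall) and ~99.7% (BRCA) against published values of 63.3% and 89.1%.
The variance rule is kept as stated rather than widened to chase those
percentages; the break-even WTP (~$130k vs published $138k) agrees.

## Numerical choices and degenerate inputs

Occupancy conservation is exact by construction; PD is clamped at zero
where extrapolated curves cross, with a warning attached to the trace when
the crossing exceeds 0.02. ICERs with a zero effect delta return signed
infinity (NaN when both deltas vanish) and dominance is classified before
any ratio is formed. Utility excursions in sensitivity analyses cap at 1.
Validation never raises: it returns findings, with errors for invariant
violations and warnings for suspicious patterns — notably the two HRD
fixtures whose PFS shape is printed equal to its scale (0.014599,
0.021614), an unrecoverable corruption that confines those subgroups to
structural rather than numeric checks.

## Known limitations

* No covariate, spline or cure-fraction survival models; no tunnel states
  or individual-level simulation.
* Costs are 2022 USD with no inflation or currency adjustment; payer
  perspective only.
* The progression-reset clock applies the OS law — nominally a
  from-randomisation quantity — from progression entry; this is a
  replication device for the source analysis, not a recommended
  epidemiological assumption, and `model_start` should be preferred for
  de-novo analyses.
* Post-second-line costs beyond the 6-cycle course are unmodelled.
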