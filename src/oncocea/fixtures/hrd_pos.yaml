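# Model inputs for the HRD-positive advanced-ovarian-cancer population.
# Maintenance olaparib + bevacizumab (intervention) vs bevacizumab (comparator).
# All costs are 2022 USD; survival time unit is months: S(t) = exp(-scale * t^shape).
subgroup: hrd_pos
settings:
  cycle_length_days: 21.0
  horizon_years: 15.0
  half_cycle_correction: true
  os_clock: progression
patient:
  body_weight: 70.0
  body_surface_area: 1.84
  serum_creatinine: 1.0
econ:
  utility_pfs: 0.840
  utility_pd: 0.790
  disutilities:
    fatigue: 0.170
    leukopenia: 0.090
    neutropenia: 0.0
    anemia: 0.0
    hypertension: 0.0
    lymphopenia: 0.0
  admin_cost_per_cycle: 124.0
  # the printed "Laboratory per cycle" row is ambiguous; read as mean 4, range 3-5
  lab_cost_per_cycle: 4.0
  imaging_cost_per_cycle: 105.0
  brca_test_cost: 2901.0
  hrd_test_cost: 4682.0
  # carboplatin 23 + paclitaxel 35 per 3-week cycle
  second_line_drug_cost_per_cycle: 58.0
  second_line_duration_cycles: 6
  bsc_cost_per_cycle: 4143.0
  terminal_care_cost: 85904.0
  discount_rate_annual: 0.03
  wtp_per_qaly: 150000.0
arms:
  intervention:
    name: olaparib plus bevacizumab
    pfs: {family: weibull, scale: 0.014599, shape: 0.014599}
    os: {family: weibull, scale: 0.0013868, shape: 1.4043253}
    olaparib_cost_per_cycle: 3657.0
    bevacizumab_cost_per_cycle: 7326.0
    olaparib_max_cycles: 35        # 2 years of 3-week cycles
    bevacizumab_max_cycles: 22     # 15 months of 3-week cycles
    ae_risks:
      fatigue: 0.050
      neutropenia: 0.060
      lymphopenia: 0.070
      anemia: 0.170
      hypertension: 0.190
    ae_management_cost: 291.0
    second_line_proportion: 0.484
  comparator:
    name: bevacizumab
    pfs: {family: weibull, scale: 0.021614, shape: 0.021614}
    os: {family: weibull, scale: 0.0014855, shape: 1.500712}
    olaparib_cost_per_cycle: 0.0
    bevacizumab_cost_per_cycle: 7326.0
    olaparib_max_cycles: 0
    bevacizumab_max_cycles: 22
    ae_risks:
      hypertension: 0.300
    ae_management_cost: 76.0
    second_line_proportion: 0.610
psa:
  - {name: intervention.ae_risks.fatigue, family: beta, mean: 0.050, low: 0.040, high: 0.060}
  - {name: intervention.ae_risks.neutropenia, family: beta, mean: 0.060, low: 0.048, high: 0.072}
  - {name: intervention.ae_risks.lymphopenia, family: beta, mean: 0.070, low: 0.056, high: 0.084}
  - {name: intervention.ae_risks.anemia, family: beta, mean: 0.170, low: 0.136, high: 0.204}
  - {name: intervention.ae_risks.hypertension, family: beta, mean: 0.190, low: 0.152, high: 0.228}
  - {name: comparator.ae_risks.hypertension, family: beta, mean: 0.300, low: 0.240, high: 0.360}
  - {name: intervention.second_line_proportion, family: beta, mean: 0.484, low: 0.387, high: 0.581}
  - {name: comparator.second_line_proportion, family: beta, mean: 0.610, low: 0.488, high: 0.732}
  # printed upper bound 1.008 clipped to the utility scale
  - {name: econ.utility_pfs, family: beta, mean: 0.840, low: 0.672, high: 1.0}
  - {name: econ.utility_pd, family: beta, mean: 0.790, low: 0.632, high: 0.948}
  - {name: econ.disutilities.leukopenia, family: beta, mean: 0.090, low: 0.072, high: 0.108}
  - {name: econ.disutilities.fatigue, family: beta, mean: 0.170, low: 0.136, high: 0.204}
  - {name: patient.body_weight, family: normal, mean: 70.0, low: 56.0, high: 84.0}
  - {name: patient.body_surface_area, family: normal, mean: 1.84, low: 1.47, high: 2.21}
  - {name: econ.discount_rate_annual, family: uniform, mean: 0.03, low: 0.0, high: 0.05}
  - {name: intervention.olaparib_cost_per_cycle, family: gamma, mean: 3657.0, low: 2926.0, high: 4388.0}
  - {name: intervention.bevacizumab_cost_per_cycle|comparator.bevacizumab_cost_per_cycle, family: gamma, mean: 7326.0, low: 5861.0, high: 8791.0}
  # carboplatin (23, 18-28) + paclitaxel (35, 28-42) sampled as their sum
  - {name: econ.second_line_drug_cost_per_cycle, family: gamma, mean: 58.0, low: 46.0, high: 70.0}
  - {name: intervention.ae_management_cost, family: gamma, mean: 291.0, low: 233.0, high: 349.0}
  - {name: comparator.ae_management_cost, family: gamma, mean: 76.0, low: 61.0, high: 91.0}
  - {name: econ.lab_cost_per_cycle, family: gamma, mean: 4.0, low: 3.0, high: 5.0}
  - {name: econ.imaging_cost_per_cycle, family: gamma, mean: 105.0, low: 84.0, high: 126.0}
  - {name: econ.admin_cost_per_cycle, family: gamma, mean: 124.0, low: 99.0, high: 149.0}
  - {name: econ.brca_test_cost, family: gamma, mean: 2901.0, low: 2321.0, high: 3481.0}
  - {name: econ.hrd_test_cost, family: gamma, mean: 4682.0, low: 3746.0, high: 5618.0}
  - {name: econ.bsc_cost_per_cycle, family: gamma, mean: 4143.0, low: 3314.0, high: 4972.0}
  - {name: econ.terminal_care_cost, family: gamma, mean: 85904.0, low: 68723.0, high: 103085.0}
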