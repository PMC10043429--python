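# Study configuration: palbociclib + fulvestrant vs placebo + fulvestrant,
# second-line HR+/HER2- advanced breast cancer, Chinese healthcare system
# perspective. All costs in USD.
settings:
  cycle_length_days: 28
  horizon_years: 10
  background_mortality_annual: 0.00718   # 2021 all-cause mortality, applied per cycle
  background_mode: per_cycle
arms:
  palbociclib:
    pfs: {family: weibull, scale: 0.06497, shape: 0.95501}
    os:  {family: weibull, scale: 0.00656, shape: 1.30497}
  placebo:
    pfs: {family: weibull, scale: 0.1405, shape: 0.8904}
    os:  {family: weibull, scale: 0.00727, shape: 1.34619}
accrual:
  follow_up_state: alive          # disease monitoring until death
  supportive_care_state: pfs      # supportive co-medication alongside therapy
  ae_mode: per_treated_cycle      # AE management cost per cycle on treatment
parameters:
  - {name: cost_palbociclib_cycle,   base: 640.39,  lower: 525.12,  upper: 768.49,  distribution: gamma}
  - {name: cost_fulvestrant_250mg,   base: 287.90,  lower: 233.77,  upper: 338.71,  distribution: gamma}
  - {name: cost_followup_cycle,      base: 166.0,   lower: 132.8,   upper: 193.02,  distribution: gamma}
  - {name: cost_administration_cycle, base: 33.56,  lower: 28.27,   upper: 40.27,   distribution: gamma}
  - {name: cost_supportive_cycle,    base: 807.0,   lower: 690.39,  upper: 953.34,  distribution: gamma}
  - {name: cost_terminal_once,       base: 1893.0,  lower: 1533.33, upper: 2209.13, distribution: gamma}
  - {name: cost_ae_neutropenia,      base: 412.0,   lower: 333.72,  upper: 468.18,  distribution: gamma}
  - {name: cost_ae_leukopenia,       base: 435.58,  lower: 378.95,  upper: 537.75,  distribution: gamma}
  - {name: cost_ae_infections,       base: 395.82,  lower: 351.49,  upper: 494.77,  distribution: gamma}
  - {name: cost_ae_fatigue,          base: 110.0,   lower: 89.50,   upper: 129.41,  distribution: gamma}
  - {name: cost_ae_nausea,           base: 323.0,   lower: 261.63,  upper: 375.58,  distribution: gamma}
  - {name: inc_palbociclib_neutropenia, base: 0.577, lower: 0.467, upper: 0.704, distribution: beta}
  - {name: inc_palbociclib_leukopenia,  base: 0.377, lower: 0.318, upper: 0.459, distribution: beta}
  - {name: inc_palbociclib_infections,  base: 0.046, lower: 0.041, upper: 0.055, distribution: beta}
  - {name: inc_palbociclib_fatigue,     base: 0.029, lower: 0.024, upper: 0.034, distribution: beta}
  - {name: inc_palbociclib_nausea,      base: 0.006, lower: 0.005, upper: 0.007, distribution: beta}
  - {name: inc_placebo_leukopenia,      base: 0.006, lower: 0.005, upper: 0.007, distribution: beta}
  - {name: inc_placebo_infections,      base: 0.035, lower: 0.028, upper: 0.043, distribution: beta}
  - {name: inc_placebo_fatigue,         base: 0.012, lower: 0.01,  upper: 0.015, distribution: beta}
  - {name: inc_placebo_nausea,          base: 0.006, lower: 0.005, upper: 0.007, distribution: beta}
  - {name: utility_pfs,              base: 0.87,    lower: 0.72,    upper: 0.96,    distribution: beta}
  - {name: utility_pd,               base: 0.71,    lower: 0.58,    upper: 0.82,    distribution: beta}
  - {name: discount_rate,            base: 0.05,    lower: 0.0,     upper: 0.08,    distribution: normal}
wtp:
  thresholds: [34138.28]   # 3x 2021 GDP per capita of China, $/QALY
  ceac_max: 120000
  ceac_step: 500
psa:
  n_draws: 1000
  seed: 2023
currency:
  unit: USD
  rmb_per_usd: 7.116
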