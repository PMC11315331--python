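provenance: synthetic
drugs:
  secukinumab:
    induction_schedule:
    - week_offset: 0
      dose_mg: 300
    - week_offset: 1
      dose_mg: 300
    - week_offset: 2
      dose_mg: 300
    - week_offset: 3
      dose_mg: 300
    - week_offset: 4
      dose_mg: 300
    maintenance_interval_weeks: 4
    maintenance_dose_mg: 300
    price_per_unit: 38459.48
    mg_per_unit: 150
    response_prob:
      PASI75: 0.7535
      PASI90: 0.7065
      PASI100: 0.3234
    annual_dropout_prob: 0.1124
    annual_relapse_prob: 0.5752
    p_serious_infection_once: 0.0257
    p_malignancy_annual: 0.0047
  ixekizumab:
    induction_schedule:
    - week_offset: 0
      dose_mg: 160
    - week_offset: 2
      dose_mg: 80
    - week_offset: 4
      dose_mg: 80
    - week_offset: 6
      dose_mg: 80
    - week_offset: 8
      dose_mg: 80
    - week_offset: 10
      dose_mg: 80
    - week_offset: 12
      dose_mg: 80
    maintenance_interval_weeks: 4
    maintenance_dose_mg: 80
    price_per_unit: 26144.3
    mg_per_unit: 80
    response_prob:
      PASI75: 0.7649
      PASI90: 0.5407
      PASI100: 0.3792
    annual_dropout_prob: 0.1159
    annual_relapse_prob: 0.8125
    p_serious_infection_once: 0.0126
    p_malignancy_annual: 0.0051
  brodalumab:
    induction_schedule:
    - week_offset: 0
      dose_mg: 210
    - week_offset: 1
      dose_mg: 210
    - week_offset: 2
      dose_mg: 210
    maintenance_interval_weeks: 2
    maintenance_dose_mg: 210
    price_per_unit: 17869.4
    mg_per_unit: 210
    response_prob:
      PASI75: 0.6402
      PASI90: 0.5127
      PASI100: 0.2468
    annual_dropout_prob: 0.2001
    annual_relapse_prob: 0.4823
    p_serious_infection_once: 0.0171
    p_malignancy_annual: 0.0098
  guselkumab:
    induction_schedule:
    - week_offset: 0
      dose_mg: 100
    maintenance_interval_weeks: 8
    maintenance_dose_mg: 100
    price_per_unit: 18306.74
    mg_per_unit: 100
    response_prob:
      PASI75: 0.8885
      PASI90: 0.7829
      PASI100: 0.4827
    annual_dropout_prob: 0.0821
    annual_relapse_prob: 0.9305
    p_serious_infection_once: 0.0179
    p_malignancy_annual: 0.002
soc:
  mtx_price_tablet: 3.494
  mtx_price_injection: 12.767
  csa_price: 8.517
  response_prob_soc: 0.4293
  p_cirrhosis_annual: 0.0027
  mtx_weekly_dose_mg: 25.0
  csa_dose_mg_per_kg_day: 5.0
  patient_weight_kg: 60.0
  mix_mtx_fraction: 0.85
  mtx_variant: tablet
  soc_lab_frequency_per_year: 4.0
utilities:
  u_baseline: 0.6399
  u_pasi75: 0.7658
  u_pasi90: 0.7689
  u_pasi100: 0.7946
  du_infection: 0.0263
  du_malignancy: 0.1093
  du_cirrhosis: 0.076
costs:
  lab_costs:
    CBC: 330.22
    FBS: 330.99
    lipid_profile: 464.17
    BUN: 131.36
    Cr: 500.79
    LFT: 425.81
    IGRA: 482.9
    CXR: 155.39
    HBsAg: 491.3
    anti_HBs: 155.23
    anti_HBc: 94.85
    AST: 520.37
    ALT: 523.71
    uric_acid: 532.1
    magnesium: 309.55
  visit_cost_direct_medical: 464.43
  nonmedical_cost_per_visit: 202.84
  visits_per_year: 8.0
  topical_cost_per_cycle: 229.98
  ae_management_costs:
    serious_infection: 70134.15
    malignancy: 184563.35
    cirrhosis: 82282.73
  cpi_factor_to_2021: 1.0
  exchange_rate_usd_per_thb: 0.0313
life_table:
  annual_death_prob:
    40: 0.001056
    41: 0.001149
    42: 0.001251
    43: 0.001362
    44: 0.001483
    45: 0.001615
    46: 0.001758
    47: 0.001914
    48: 0.002084
    49: 0.002269
    50: 0.00247
    51: 0.002689
    52: 0.002928
    53: 0.003187
    54: 0.00347
    55: 0.003778
    56: 0.004113
    57: 0.004478
    58: 0.004876
    59: 0.005308
    60: 0.005779
    61: 0.006292
    62: 0.00685
    63: 0.007458
    64: 0.008119
    65: 0.00884
    66: 0.009624
    67: 0.010478
    68: 0.011407
    69: 0.012419
    70: 0.013521
    71: 0.01472
    72: 0.016026
    73: 0.017448
    74: 0.018996
    75: 0.020681
    76: 0.022516
    77: 0.024514
    78: 0.026689
    79: 0.029056
    80: 0.031634
    81: 0.034441
    82: 0.037496
    83: 0.040823
    84: 0.044444
    85: 0.048387
    86: 0.05268
    87: 0.057354
    88: 0.062442
    89: 0.067981
    90: 0.074013
    91: 0.080579
    92: 0.087727
    93: 0.09551
    94: 0.103984
    95: 0.113209
    96: 0.123252
    97: 0.134187
    98: 0.146092
    99: 0.159053
    100: 0.173163
  rr_psoriasis: 1.483
settings:
  discount_rate_annual: 0.03
  cycle_length_days: 14.0
  start_age: 40
  horizon_age: 100
  wtp_thb_per_qaly: 160000.0
  response_definition: PASI75
  assessment_months: 6.0
  stop_years: 3.0
  stop_clock: per_line
  half_cycle_correction: false
psa_specs:
- path: drugs.secukinumab.response_prob.PASI75
  family: beta
  params: {}
- path: drugs.secukinumab.annual_dropout_prob
  family: beta
  params: {}
- path: drugs.secukinumab.annual_relapse_prob
  family: beta
  params: {}
- path: drugs.secukinumab.price_per_unit
  family: gamma
  params: {}
- path: drugs.ixekizumab.response_prob.PASI75
  family: beta
  params: {}
- path: drugs.ixekizumab.annual_dropout_prob
  family: beta
  params: {}
- path: drugs.ixekizumab.annual_relapse_prob
  family: beta
  params: {}
- path: drugs.ixekizumab.price_per_unit
  family: gamma
  params: {}
- path: drugs.brodalumab.response_prob.PASI75
  family: beta
  params: {}
- path: drugs.brodalumab.annual_dropout_prob
  family: beta
  params: {}
- path: drugs.brodalumab.annual_relapse_prob
  family: beta
  params: {}
- path: drugs.brodalumab.price_per_unit
  family: gamma
  params: {}
- path: drugs.guselkumab.response_prob.PASI75
  family: beta
  params: {}
- path: drugs.guselkumab.annual_dropout_prob
  family: beta
  params: {}
- path: drugs.guselkumab.annual_relapse_prob
  family: beta
  params: {}
- path: drugs.guselkumab.price_per_unit
  family: gamma
  params: {}
- path: utilities.u_baseline
  family: beta
  params:
    se: 0.03
- path: utilities.u_pasi75
  family: beta
  params:
    se: 0.03
- path: utilities.u_pasi90
  family: beta
  params:
    se: 0.03
- path: utilities.u_pasi100
  family: beta
  params:
    se: 0.03
- path: soc.response_prob_soc
  family: beta
  params: {}
- path: costs.visit_cost_direct_medical
  family: gamma
  params: {}
- path: life_table.rr_psoriasis
  family: lognormal
  params:
    se: 0.1
alt_utilities:
  u_baseline: 0.6399
  u_pasi75: 0.791
  u_pasi90: 0.7941
  u_pasi100: 0.8198
  du_infection: 0.0263
  du_malignancy: 0.1093
  du_cirrhosis: 0.076
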