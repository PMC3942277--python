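event_rates_vka:
  ischemic_stroke: 0.004
  myocardial_infarction: 0.0028
  systemic_embolism: 0.0005
  intracranial_bleed: 0.0019
  minor_extracranial_bleed: 0.0297
  major_extracranial_bleed: 0.0069
event_rates_secondline:
  ischemic_stroke: 0.008
  myocardial_infarction: 0.0028
  systemic_embolism: 0.001
  intracranial_bleed: 0.00095
  minor_extracranial_bleed: 0.01485
  major_extracranial_bleed: 0.00345
effect:
  rr_is:
    point: 0.94
    lo: 0.75
    hi: 1.17
  rr_mi:
    point: 0.81
    lo: 0.63
    hi: 1.06
  rr_se:
    point: 0.23
    lo: 0.09
    hi: 0.61
  rr_ic:
    point: 0.67
    lo: 0.47
    hi: 0.93
  rr_major_ec:
    point: 1.14
    lo: 0.98
    hi: 1.33
  rr_minor_ec:
    point: 1.04
    lo: 0.96
    hi: 1.13
  population_tag: SOT
mortality:
  case_fatality_major_stroke: 0.126
  case_fatality_minor_stroke: 0.0
  case_fatality_major_bleed: 0.016
  case_fatality_minor_bleed: 0.0
  case_fatality_ic_bleed: 0.388
  case_fatality_se: 0.0
  case_fatality_mi: 0.0969
  post_major_stroke_excess: 0.026
  post_minor_stroke_excess: 0.0
  post_ic_excess: 0.026
  post_mi_excess: 0.0268
  life_table:
    '75': 0.03
    '76': 0.03348834211376614
    '77': 0.03738230191762142
    '78': 0.041729043853913406
    '79': 0.046581216555340074
    '80': 0.051997590536021855
    '81': 0.058043770032060946
    '82': 0.06479298761354746
    '83': 0.07232699119251629
    '84': 0.08073703417047785
    '85': 0.090124980718393
    '86': 0.10060453957647071
    '87': 0.11230264131782587
    '88': 0.1253609757576974
    '89': 0.13993770812964376
    '90': 0.15620939481539545
    '91': 0.17437312183207765
    '92': 0.19464889197860136
    '93': 0.21728228955483037
    '94': 0.24254745492915175
    '95': 0.27075040498302366
    '96': 0.3022327396504076
    '97': 0.3373757794464553
    '98': 0.37660518410004684
    '99': 0.42039610823200846
    '100': 0.4692789565256451
    '101': 0.5238458080973997
    '102': 0.5847575878809336
    '103': 0.6527520718859124
    '104': 0.7286528232928366
    '105': 0.8133791676197365
    '106': 0.9079573277820026
    '107': 1.0
    '108': 1.0
    '109': 1.0
    '110': 1.0
  start_age: 75
utilities:
  baseline: 0.779
  vka_multiplier: 0.95
  vka_disutility_mode: multiplicative
  acute_major_is: 0.189
  acute_minor_is: 0.641
  acute_mi: 0.68
  acute_minor_bleed: 0.776
  acute_major_bleed: 0.598
  acute_ic: 0.6
  acute_se: 0.66
  post_minor_is: 0.72
  post_major_is: 0.48
  post_mi: 0.69
  post_ic: 0.74
costs:
  drug_daily_riva: 2.16
  drug_daily_vka: 0.05
  drug_daily_secondline: 0.0
  visit_cost_vka_first: 32.0
  visit_cost_vka_subsequent: 22.0
  visit_cost_other: 10.0
  inr_test_cost: 0.0
  acute_minor_is: 900.0
  acute_moderate_is: 1625.0
  acute_severe_is: 2475.0
  acute_se: 1567.0
  acute_ic: 2475.0
  acute_minor_ec: 257.0
  acute_major_ec: 654.0
  acute_mi: 1783.0
  followup_major_stroke: 1093.0
  followup_ic: 1093.0
  followup_mi: 1296.0
  transport_cost_per_visit: 70.0
  transport_uptake: 0.5
  rebate_entry: 0.0
  rebate_volume: 0.0
  copay_rate: 0.25
  maintenance_visits_per_cycle_vka: 3.0
  other_visits_per_cycle: 0.25
persistence:
  disc_first_cycle_riva: 0.089
  disc_first_cycle_vka: 0.08
  disc_subsequent_riva: 0.0439
  disc_subsequent_vka: 0.0446
  second_line: aspirin
  ic_bleed_discontinuation_prob: 1.0
settings:
  discount_rate_annual: 0.035
  terminal_age: 110
  wtp_grid:
  - 0.0
  - 5000.0
  - 10000.0
  - 15000.0
  - 20000.0
  - 25000.0
  - 30000.0
  - 35000.0
  - 40000.0
  - 45000.0
  - 50000.0
  - 55000.0
  - 60000.0
  - 65000.0
  - 70000.0
  - 75000.0
  - 80000.0
  - 85000.0
  - 90000.0
  - 95000.0
  - 100000.0
  stroke_major_fraction: 0.7
  major_stroke_cost_weights:
    severe: 1.0
  minor_stroke_cost_weights:
    minor: 1.0
  half_cycle_correction: false
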