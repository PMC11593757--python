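n_persons: 2000
start_month: 2018-11
end_month: 2024-03
age_mix:
  18-39: 0.416
  40-59: 0.324
  60-79: 0.21
  80+: 0.05
sex_mix:
  female: 0.503
  male: 0.497
ethnicity_mix:
  White: 0.777
  Asian: 0.11
  Black: 0.042
  Mixed: 0.017
  Other/Unknown: 0.054
imd_mix:
  1: 0.201
  2: 0.213
  3: 0.205
  4: 0.195
  5: 0.186
baseline_log_rate:
  bp: -2.162823150618887
  hba1c: -2.8134107167600364
age_effect:
  18-39: 0.0
  40-59: 0.35
  60-79: 0.75
  80+: 0.95
sex_effect:
  female: 0.0
  male: -0.05
ethnicity_effect:
  White: 0.0
  Asian: 0.1
  Black: 0.05
  Mixed: 0.0
  Other/Unknown: -0.05
imd_effect:
  1: 0.05
  2: 0.03
  3: 0.0
  4: -0.02
  5: -0.03
seasonal_amplitude:
  bp: 0.1
  hba1c: 0.1
seasonal_phase:
  bp: 10.0
  hba1c: 10.0
annual_trend: -0.02
disruption:
  bp:
    depth: 0.3
    onset: 2020-03
    half_life: 10.0
    post_offset: -0.16
  hba1c:
    depth: 0.35
    onset: 2020-03
    half_life: 5.0
    post_offset: 0.05
dispersion_phi: 1.5
dup_prob: 0.05
valueless_prob: 0.05
contaminants:
  under18: 0.25
  unknown_sex: 3.0e-05
  missing_imd: 0.004
  short_followup: 0.0001
death_hazard:
  18-39: 5.0e-05
  40-59: 0.0002
  60-79: 0.0015
  80+: 0.008
seed: 0
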