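# Modified renal angina index: SUM of applicable local risk-factor weights ×
# the creatinine-based injury score only.  The weights below are synthetic
# placeholders chosen so the maximum risk sum is 20 (maximum score 160); the
# engine is agnostic to the exact local weight set.
risk_weights:
  icu_admission: 1
  sepsis_admission: 7
  ventilation_and_vasopressors: 5
  severe_malaria_admission: 4
  age_under_5: 3
injury_dscr_tiers:
  - {lower: 1.0, score: 2, inclusive: false}
  - {lower: 1.5, score: 4, inclusive: true}
  - {lower: 2.0, score: 8, inclusive: true}
injury_fo_tiers:
  - {lower: 5.0, score: 2, inclusive: true}
  - {lower: 10.0, score: 4, inclusive: true}
  - {lower: 15.0, score: 8, inclusive: true}
positivity_cutoff: 8
mrai_mode: true
schwartz_k_umol_cm: 36.5
assumed_ecrcl: 120.0
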