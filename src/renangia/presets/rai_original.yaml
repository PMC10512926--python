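# Original renal angina index: highest applicable risk stratum × max of the
# creatinine and fluid-overload injury tiers; positive at a product >= 8.
risk_weights:
  icu_admission: 1
  transplant_history: 3
  ventilation_and_vasopressors: 5
injury_dscr_tiers:
  - {lower: 1.0, score: 2, inclusive: false}
  - {lower: 1.5, score: 4, inclusive: true}
  - {lower: 2.0, score: 8, inclusive: true}
injury_fo_tiers:
  - {lower: 5.0, score: 2, inclusive: true}
  - {lower: 10.0, score: 4, inclusive: true}
  - {lower: 15.0, score: 8, inclusive: true}
positivity_cutoff: 8
mrai_mode: false
schwartz_k_umol_cm: 36.5
assumed_ecrcl: 120.0
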