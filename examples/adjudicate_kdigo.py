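"""Adjudicate KDIGO stage and severe AKI on a synthetic cohort.

Severe AKI (the screening outcome) is KDIGO stage >= 2: day-3 creatinine at
least double the baseline, oliguria <= 0.5 mL/kg/h for >= 8 h, or renal
replacement therapy.
"""

from renangia import CohortConfig, adjudicate_cohort, generate, kdigo_stage
from renangia.diagnostics import round_half_up

# single-patient staging
for baseline, day3, note in [(30.0, 48.0, "1.6x"), (30.0, 66.0, "2.2x"), (30.0, 95.0, "3.2x")]:
    a = kdigo_stage(baseline, day3)
    print(f"baseline {baseline} -> day 3 {day3} ({note}): stage {a.stage}, "
          f"severe={a.severe}, basis={a.basis}")

# whole-cohort prevalence
records = generate(CohortConfig(seed=1, fixed_margin_mode=True))
adjudication = adjudicate_cohort(records)
lo, hi = adjudication.prevalence_ci()
print(f"\ncohort: {adjudication.n_severe}/{adjudication.n_assessed} severe AKI, "
      f"prevalence {round_half_up(adjudication.prevalence * 100, 1)}% "
      f"(95% CI {round_half_up(lo * 100, 1)}-{round_half_up(hi * 100, 1)})")
print(f"any-stage AKI: {adjudication.n_aki} "
      f"({round_half_up(adjudication.aki_proportion * 100, 1)}%)")
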