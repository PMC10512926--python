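# renangia

Renal angina index scoring, KDIGO severe-AKI adjudication, and
diagnostic-precision evaluation for pediatric intensive-care cohorts.

## The problem

Acute kidney injury (AKI) in critically ill children is staged by the KDIGO
criteria from serum creatinine rise and urine output, but creatinine is a
late marker. The **renal angina index (RAI)** is a day-of-admission screen
for the risk of developing *severe* AKI (KDIGO stage ≥ 2) by day 3. It is
the product of two strata:

```
RAI = Risk × Injury
Risk   ∈ {1, 3, 5}    — ICU admission (1), transplant history (3),
                         mechanical ventilation AND vasopressors within 8 h (5)
Injury ∈ {1, 2, 4, 8} — max of the ΔSCr tier and the %FO tier
ΔSCr  = day-0 SCr / baseline SCr   (1 → 1, (1,1.5) → 2, [1.5,2) → 4, ≥2 → 8)
%FO   = (fluid in − fluid out) / admission weight × 100
                                   (<5 → 1, [5,10) → 2, [10,15) → 4, ≥15 → 8)
```

A product ≥ 8 is "renal angina positive". When no measured baseline
creatinine exists it is imputed from height by inverting the
height-based clearance estimate at an assumed eCrCl of 120 mL/min/1.73 m²
(BSCr = 36.5 µmol·cm⁻¹ × height / 120). A **modified index (mRAI)**
replaces the max-stratum risk with the *sum* of locally weighted risk
factors, multiplied by the creatinine injury tier only.

The package provides, as a library with a thin `renangia` CLI on top:

- `renangia.scoring` — ΔSCr, %FO, baseline imputation, original and
  modified index, achievable-score enumeration (`rai_original` /
  `mrai_local` presets, YAML-configurable tiers and weights);
- `renangia.kdigo` — KDIGO staging (creatinine ratio, 48-h absolute rise,
  oliguria ≤ 0.5 mL/kg/h for ≥ 8 h, RRT) and cohort adjudication;
- `renangia.diagnostics` — confusion metrics with **untruncated Wald 95%
  CIs** (upper bounds may exceed 100%), cutoff scans with Youden's J,
  empirical ROC/AUC (Mann–Whitney, ties = ½), and DeLong's paired-AUC
  z-test;
- `renangia.synthetic` — a seedable synthetic PICU cohort generator with an
  exact fixed-margin mode, so the whole pipeline is testable without
  patient data;
- `renangia.pipeline` / `renangia.cli` — validate → score → adjudicate →
  evaluate → report.

## Worked example

```python
from renangia import (CohortConfig, generate, compute_rai, rai_original,
                      adjudicate_cohort, confusion_from_cohort, screening_metrics)

records = generate(CohortConfig(seed=1, fixed_margin_mode=True))  # 122 patients
config = rai_original()
results = [compute_rai(r, config) for r in records]
severe = [a.severe for a in adjudicate_cohort(records, config).assessments]

cm = confusion_from_cohort([r.positive for r in results], severe)
m = screening_metrics(cm)
print(cm)
print(f"sens {m.sensitivity}  spec {m.specificity}  PPV {m.ppv}  NPV {m.npv}")
```

prints

```
ConfusionMatrix(tp=10, fp=15, fn=8, tn=89)
sens 55.6(32.6–78.5)  spec 85.6(78.8–92.3)  PPV 40.0(20.8–59.2)  NPV 91.8(86.3–97.2)
```

Ten of the 18 children who developed severe AKI screened positive on day 0
(sensitivity 55.6%), while 89 of 104 who did not screened negative
(specificity 85.6%). The high NPV (91.8%) is the index's purpose: a
negative screen argues strongly against severe AKI by day 3. Each value in
parentheses is an untruncated Wald 95% CI in percent.

The `examples/` directory holds one short script per capability
(simulation, scoring, adjudication, screening evaluation, DeLong
comparison, full pipeline), each printing the numbers it computes. The same
operations are available from the shell:

```sh
renangia simulate --fixed-margins --seed 1 --out cohort.csv
renangia run --cohort cohort.csv --out-dir out
```

## Cohort CSV dialect

One row per patient; header columns are exactly the field names of
`renangia.PatientRecord` (`patient_id`, `age_years`, `sex`, `height_cm`,
`weight_kg`, `diagnosis_category`, clinical flags, `baseline_scr_umol_l`,
`d0_scr_umol_l`, `d3_scr_umol_l`, fluids in litres, outcomes); an empty
cell means missing; UTF-8. Creatinine is µmol/L throughout
(`renangia.records.scr_mg_dl_to_umol_l` converts at the I/O boundary).

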