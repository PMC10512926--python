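# Methods

## Scoring model

The renal angina index multiplies a contextual risk stratum by a functional
injury stratum on day 0 of a PICU admission. Risk strata (original
convention: the single highest applicable weight) are ICU admission (1),
transplant history (3), and concurrent mechanical ventilation and
vasopressor support within 8 h (5). Injury is the larger of two tiered
signals:

- **ΔSCr**, the day-0 / baseline creatinine fold-change. Tier boundaries
  are closed on the left and open on the right, with the lowest boundary
  open: exactly 1.0 ("no change") scores 1, (1.0, 1.5) scores 2,
  [1.5, 2.0) scores 4, ≥ 2.0 scores 8. This matches the strata in which
  cohort tables are conventionally printed (">1×–1.49×", "1.5×–1.99",
  "≥2×").
- **%FO**, percent fluid overload over the first 8 h:
  (in − out)/weight × 100 with fluids in litres, which places the value in
  the clinical 0–25% range. Tiers: <5 → 1, [5, 10) → 2, [10, 15) → 4,
  ≥ 15 → 8. A missing fluid balance degrades injury scoring to ΔSCr alone
  and flags the result (`fo_available=False`) rather than erroring or
  imputing zero — in low-resource units the majority of admissions lack
  fluid documentation, and a silent zero would bias positivity downward.

The modified index (mRAI) sums the weights of all applicable local risk
factors and multiplies by the creatinine injury tier only. The bundled
`mrai_local` preset uses placeholder weights — ICU 1, sepsis 7,
ventilation+vasopressors 5, severe malaria 4, age ≤ 5 years 3 — chosen so
the maximum risk sum is 20 (maximum score 160). The exact local weight set
is a site-specific calibration; the engine validates any weight map over
the named risk predicates and `enumerate_achievable_scores` exposes the
resulting score lattice by exhaustive subset enumeration.

### Baseline imputation

When no measured baseline creatinine exists within the look-back window it
is imputed by inverting the height-based creatinine-clearance estimate
eCrCl = k·height/SCr at an assumed clearance of 120 mL/min/1.73 m²:
BSCr = k · height / 120, with k = 36.5 µmol·cm⁻¹ (0.413 mg/dL·cm⁻¹ ×
88.4). Both k and the assumed clearance are `ScoreConfig` fields. Imputed
baselines are flagged on every result.

## Severity adjudication

Severe AKI is KDIGO stage ≥ 2 on day 3. Staging uses the day-3/baseline
creatinine ratio (1.5–1.9× → 1, 2.0–2.9× → 2, ≥ 3× → 3), an absolute rise
of ≥ 26.5 µmol/L within 48 h (stage 1, applied only when a 48-h-spaced
pair exists — day 0 and day 3 are 72–96 h apart, so cohort adjudication
does not use it), oliguria ≤ 0.5 mL/kg/h sustained ≥ 8 h (stage 2; the
KDIGO-standard 12-h window is available via `uo_severe_hours`), and RRT
receipt (stage 3). "An increase of 200% from baseline" is interpreted as
*reaching* 2.0× baseline, consistent with the KDIGO stage-2 band; reading
it as a 200% rise (3×) would collapse stages 2 and 3. A ≥ 50% fall in
estimated clearance is algebraically identical to creatinine doubling at
fixed height (eCrCl ∝ 1/SCr), which the property suite asserts on random
inputs. Patients without urine-output documentation are staged on
creatinine alone.

## Diagnostic evaluation

- **Confidence intervals.** Untruncated Wald, p ± 1.96·√(p(1−p)/n), with
  z = 1.96 exactly (not Φ⁻¹(0.975)); upper bounds above 100% are reported
  as computed, which is the convention of the tables this package
  reproduces. Wilson and Clopper–Pearson are available behind
  `ci_method=`. Percentages are rounded half-up to 1 decimal place at the
  display edge only; internal values stay raw.
- **Cutoff scans.** "Score ≥ cutoff" is positive. Youden's
  J = sens + spec − 1, displayed to 2 decimals; the optimal cutoff
  maximises J with ties broken toward the smallest cutoff, favouring
  sensitivity in a screening context.
- **ROC/AUC.** Empirical curve over all distinct score values; AUC by the
  Mann–Whitney rank formulation with ties counted ½. Equivalence with an
  O(n²) concordance count and with scikit-learn is asserted in tests.
- **DeLong comparison.** Covariance of two paired AUC estimators from
  placement values; z = ΔAUC/SE, two-sided normal p, 95% CI on the
  difference. Identical scores yield ΔAUC = 0 with zero variance, reported
  as z = 0, p = 1 rather than 0/0. The test suite checks the z statistic
  against a 10,000-replicate paired bootstrap on a 200-patient synthetic
  cohort (10% relative tolerance, fixed seeds).

## Synthetic cohorts

The generator emulates the *statistical* structure of a 122-patient
low-resource PICU cohort — severe-AKI prevalence 18/122, renal-angina
positivity 10/18 given severe AKI and 15/104 otherwise, elevated day-0
creatinine 16/18 and 66/104, mortality 7/18 and 13/104, 29.5% infants, one
RRT recipient, ~61% missing fluid documentation — not renal physiology.
Trajectories are synthesized backward from sampled labels: the sampled
injury tier fixes the day-0 fold-change (representative values 1.0, 1.25,
1.7, 2.2), severity fixes the day-3 ratio (≥ 2.05 when severe, < 1.95
otherwise), and the baseline comes from a rough height-for-age growth
model (heights rounded *before* the baseline is derived, so downstream
imputation recovers the exact value the trajectory was built from). Fluid
balances, when present, are kept under the 5% tier so they never perturb a
sampled injury tier. Re-scoring and re-adjudicating a generated cohort
therefore recovers the sampled labels exactly; `round_trip_check` enforces
this, and the suite sweeps it over 100 seeds.

Fixed-margin mode lays the 122 label rows out deterministically (the seed
still drives demographics and jitter); one internal inconsistency in the
printed source tables — the non-severe ΔSCr strata sum to 67 elevated
patients while the elevated-creatinine margin prints 66 — is resolved in
favour of the margin (strata 38/39/27/0), since the margin is what the
screening-metric tables are computed from. Length-of-stay and ventilation
days use fixed representative values in fixed mode and negative-binomial
draws (medians ≈ 6 and ≈ 3 days) in stochastic mode; the exact count
family is a free choice and nothing downstream depends on it.

What passing tests on synthetic cohorts do **not** show: calibration of
the index on real patients, robustness to assay noise in creatinine, or
the behaviour of %FO scoring under realistic fluid-therapy dynamics — the
generator never produces a patient whose positivity hinges on fluid
overload alone.

## Numerical and design choices

- Creatinine is µmol/L everywhere inside the package; mg/dL conversion
  (× 88.4) exists only at the I/O boundary.
- Rounding is half-up (Decimal-based, with a pre-round at 7 extra digits to
  neutralise float artifacts such as 0.485 representing as 0.48499…93).
- "Age ≤ 5 years" subgroup filters are inclusive of exactly 5.0.
- Pipeline outputs are a pure function of (input CSV, analytic config,
  seed); the run summary embeds a SHA-256 of the analytic config
  (excluding file paths) so reruns can be verified byte-for-byte. Partial
  outputs are deleted if a run fails.
- The problem sizes used by the test and acceptance runs — the 122-patient
  fixed-margin cohort for exact tables, n = 200 with 10,000 bootstrap
  replicates for the DeLong check, n = 10,000 for stochastic-conditional
  convergence, 100 seeds for the round-trip sweep — were chosen as the
  smallest sizes at which each check is statistically meaningful.

## Known limitations

- The mRAI weight preset is a synthetic placeholder, not a validated local
  calibration; sites must supply their own weights.
- Cohort adjudication ignores the 48-h absolute-rise criterion by
  construction of the two-sample (day 0, day 3) data model.
- The logistic-regression risk-factor analysis sometimes reported
  alongside screening tables is out of scope, as are severity-of-illness
  scores (PRISM III) and any urine-output-based injury signal on day 0.
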