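"""Evaluate the renal angina index as a screen for severe AKI.

Cross-tabulates day-0 positivity against day-3 severe AKI on the
fixed-margin cohort and prints the screening metrics with untruncated Wald
95% intervals, a cutoff scan with Youden's J, and the empirical AUC.
"""

from renangia import (
    CohortConfig,
    adjudicate_cohort,
    compute_rai,
    confusion_from_cohort,
    cutoff_scan,
    generate,
    rai_original,
    roc_auc,
    screening_metrics,
)
from renangia.diagnostics import round_half_up

records = generate(CohortConfig(seed=1, fixed_margin_mode=True))
config = rai_original()
results = [compute_rai(r, config) for r in records]
severe = [a.severe for a in adjudicate_cohort(records, config).assessments]

cm = confusion_from_cohort([r.positive for r in results], severe)
m = screening_metrics(cm)
print(f"confusion: TP {cm.tp}, FN {cm.fn}, FP {cm.fp}, TN {cm.tn}")
print(f"sensitivity {m.sensitivity}  specificity {m.specificity}")
print(f"PPV {m.ppv}  NPV {m.npv}")
# the high NPV is the index's point: a negative screen argues against
# severe AKI developing by day 3

scores = [r.rai for r in results]
print("\ncutoff scan (positive means score >= cutoff):")
scan = cutoff_scan(scores, severe, [8, 10, 12])
for row in scan:
    print(f"  >= {row.cutoff:>2}: sens {row.metrics.sensitivity.pct}%, "
          f"spec {row.metrics.specificity.pct}%, J = {row.youden_2dp:.2f}")
print(f"best cutoff by Youden's J: >= {scan.best_cutoff}")

roc = roc_auc(scores, severe)
print(f"\nAUC {round_half_up(roc.auc, 2)} "
      f"({roc.n_pos} severe vs {roc.n_neg} non-severe)")
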