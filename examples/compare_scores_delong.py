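"""Compare two paired AUCs with DeLong's nonparametric z-test.

Both scores are computed on the same patients, so their AUC estimators are
correlated; DeLong's method estimates the covariance from placement values
and tests the difference.  Here the original index is compared against a
noise-degraded copy of itself, so the true difference is real but modest.
"""

import numpy as np

from renangia import (
    CohortConfig,
    adjudicate_cohort,
    compute_rai,
    delong_compare,
    generate,
    rai_original,
)

records = generate(CohortConfig(seed=11, n_patients=200))
config = rai_original()
scores = np.array([compute_rai(r, config).rai for r in records], dtype=float)
severe = [a.severe for a in adjudicate_cohort(records, config).assessments]

rng = np.random.default_rng(42)
degraded = scores + rng.normal(0.0, 3.0, scores.size)

cmp = delong_compare(scores, degraded, severe)
print(f"AUC (index) = {cmp.auc_a:.3f},  AUC (degraded) = {cmp.auc_b:.3f}")
print(f"difference {cmp.diff:+.3f} (95% CI {cmp.ci_diff[0]:+.3f} to {cmp.ci_diff[1]:+.3f})")
print(f"z = {cmp.z:.3f}, two-sided p = {cmp.p_two_sided:.3f}")
# |z| < 1.96 means the paired AUCs are statistically indistinguishable at
# the 5% level on this cohort size
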