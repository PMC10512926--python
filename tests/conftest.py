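import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from renangia import adjudicate_cohort, compute_rai, rai_original
from renangia.synthetic import CohortConfig, generate_with_labels

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixed_cohort():
    """The deterministic fixed-margin cohort with its sampled label table."""
    return generate_with_labels(CohortConfig(seed=1, fixed_margin_mode=True))


@pytest.fixture(scope="session")
def fixed_scored(fixed_cohort):
    """Fixed-margin cohort scored with the original index and adjudicated."""
    records, labels = fixed_cohort
    config = rai_original()
    results = [compute_rai(r, config) for r in records]
    adjudication = adjudicate_cohort(records, config)
    positives = np.array([r.positive for r in results])
    severe = np.array([a.severe for a in adjudication.assessments])
    elevated = np.array([r.delta_scr > 1.0 for r in results])
    return records, labels, results, adjudication, positives, severe, elevated
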