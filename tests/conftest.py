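import numpy as np
import pytest

from arcsync.arc import default_template
from arcsync.synthetic import (
    CohortConfig,
    make_arc_engagement,
    make_eeg_cohort,
    scaled_template,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition synthetic cohort (8 subjects, 8 channels, 120 s)."""
    tmpl = scaled_template(120.0)
    _, truth = make_arc_engagement(tmpl, 200.0, 2, 0.0, seed=0)
    config = CohortConfig(seed=0)
    cohort, ground_truth = make_eeg_cohort(config, truth)
    return cohort, ground_truth, config


@pytest.fixture(scope="session")
def tiny_cohort():
    """Short low-cost cohort for structural checks."""
    tmpl = scaled_template(20.0)
    _, truth = make_arc_engagement(tmpl, 200.0, 2, 0.0, seed=1)
    config = CohortConfig(n_subjects=3, duration_s=20.0, seed=1)
    cohort, ground_truth = make_eeg_cohort(config, truth)
    return cohort, ground_truth, config


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
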