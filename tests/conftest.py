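import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from movecoda import TrialConfig, generate_trial
from movecoda.preprocess import (
    PART_COLS,
    aggregate_subject_timepoint,
    filter_participants,
    filter_valid_days,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_compositions(rng, n, d=4):
    """Strictly positive random part vectors with broad log-scale spread."""
    return np.exp(rng.normal(0.0, 1.5, size=(n, d)))


@pytest.fixture(scope="session")
def small_trial():
    """A compact clean trial (no corrupt records) for fast end-to-end tests."""
    cfg = TrialConfig(
        n_intervention=40,
        n_control=40,
        invalid_day_rate=0.0,
        missing_rate=0.0,
        sublimit_rate=0.0,
        seed=11,
    )
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def analysis_dataset(small_trial):
    """Analysis-ready subject-timepoint compositions plus covariates."""
    days, _ = filter_valid_days(small_trial.days)
    days, subjects, _ = filter_participants(days, small_trial.subjects)
    analysis = aggregate_subject_timepoint(days)
    return analysis, subjects
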