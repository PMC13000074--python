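import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from phenoguide.preprocessing import preprocess
from phenoguide.synthetic_cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient simulated cohort shared across unit tests."""
    cfg = default_config(n_patients=150, seed=5)
    events, admissions, truth = generate_cohort(cfg)
    return cfg, events, admissions, truth


@pytest.fixture(scope="session")
def small_splits(small_cohort):
    _, events, admissions, _ = small_cohort
    splits, stats, report = preprocess(events, admissions, split_seed=5)
    return splits, stats, report


def make_events(rows):
    """rows: (patient_id, time_offset_hours, variable, value)."""
    return pd.DataFrame(
        rows, columns=["patient_id", "time_offset_hours", "variable", "value"]
    )


def make_admissions(rows):
    """rows: (patient_id, los_hours, age, weight, height, gender, died_90d)."""
    return pd.DataFrame(
        rows,
        columns=["patient_id", "los_hours", "age", "weight", "height", "gender", "died_90d"],
    )


@pytest.fixture
def events_factory():
    return make_events


@pytest.fixture
def admissions_factory():
    return make_admissions
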