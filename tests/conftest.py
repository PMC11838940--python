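"""Shared fixtures: hand-built micro-cohorts and simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from teco.data_model import CohortSchema, validate_cohort
from teco.preprocess import fit_feature_schema
from teco.synthetic import preset, simulate_cohort


def make_micro_cohort():
    """Two encounters with hand-placed measurements (values chosen by hand)."""
    measurements = pd.DataFrame(
        {
            "encounter_id": ["a", "a", "a", "a", "b", "b"],
            "variable": ["sf_ratio", "sf_ratio", "msofa", "temperature", "sf_ratio", "msofa"],
            "t_minutes": [3.0, 7.0, 40.0, 70.0, 10.0, 50.0],
            "value": [400.0, 380.0, 5.0, 37.1, 350.0, 7.0],
        }
    )
    baseline = pd.DataFrame(
        {
            "encounter_id": ["a", "b"],
            "age": [60.0, 70.0],
            "sex": ["Male", "Female"],
            "race": ["White", "Black"],
            "ethnicity": ["Hispanic", "Unknown"],
            "bmi": [28.0, np.nan],
            "outcome": ["discharge", "death"],
            "outcome_time_minutes": [10000.0, 7200.0],
        }
    )
    return validate_cohort(measurements, baseline, CohortSchema())


@pytest.fixture
def micro_cohort():
    return make_micro_cohort()


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong planted-signal cohort shared by the slower integration tests."""
    cohort, gt = simulate_cohort(preset("strong-signal-small", seed=11))
    return cohort, gt


@pytest.fixture(scope="session")
def strong_schema(strong_cohort):
    cohort, _ = strong_cohort
    return fit_feature_schema(cohort)
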