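"""Shared fixtures: hand-built micro-cohorts and medium simulated cohorts.

Everything is generated programmatically; the medium cohorts are session-
scoped because several test modules reuse them.
"""

import numpy as np
import pandas as pd
import pytest

from ppcvd.cohort import generate_cohort
from ppcvd.defaults import default_spec


@pytest.fixture(scope="session")
def six_subject_cohort() -> pd.DataFrame:
    """Six subjects, one binary covariate, no tied times."""
    return pd.DataFrame(
        {
            "x": [1, 1, 1, 0, 0, 0],
            "time": [1.0, 4.0, 6.0, 2.0, 5.0, 8.0],
            "event": [1, 0, 1, 1, 0, 1],
        }
    )


@pytest.fixture(scope="session")
def five_subject_cohort() -> pd.DataFrame:
    """Five subjects for hand Kaplan-Meier / Nelson-Aalen checks."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0],
            "event": [1, 0, 1, 1, 0],
        }
    )


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """Default study conditions, n = 60,000, horizon-only censoring.

    Large enough for parameter-recovery and in-sample calibration
    properties at ~600 events, small enough to fit in the test budget.
    """
    spec = default_spec(n=60_000, seed=20240, missingness=False, censoring=None)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def medium_censored_cohort() -> pd.DataFrame:
    """As medium_cohort but with the default censoring mechanism."""
    spec = default_spec(n=60_000, seed=20241, missingness=False)
    return generate_cohort(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
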