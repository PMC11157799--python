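import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from syndromic.cohort import default_calibration, generate_cohort_frame
from syndromic.scores import classify_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Classified default-calibration cohort at the published size."""
    frame = generate_cohort_frame(default_calibration())
    return classify_cohort(frame)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Classified 2,000-patient cohort for cheap end-to-end tests."""
    frame = generate_cohort_frame(default_calibration(n_patients=2000, seed=5))
    return classify_cohort(frame)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
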