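import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from saccsdt.synthetic_data import SessionParams, generate_session, trials_to_frame

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_session_frame() -> pd.DataFrame:
    """One seeded control session (10 trials/condition) as a tidy table."""
    params = SessionParams(seed=7, n_trials_per_condition=10)
    return trials_to_frame(generate_session(params), session_id=0, perturbation="control")


@pytest.fixture(scope="session")
def medium_session_frame() -> pd.DataFrame:
    """A larger seeded control session (200 trials/condition)."""
    params = SessionParams(seed=11, n_trials_per_condition=200)
    return trials_to_frame(generate_session(params), session_id=0, perturbation="control")
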