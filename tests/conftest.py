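import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from urgentsaccade.race import RaceParams, predicted_tachometric

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> RaceParams:
    return RaceParams.default()


@pytest.fixture(scope="session")
def cas_curve(default_params):
    """Model-predicted antisaccade tachometric curve, 5e4 trials."""
    return predicted_tachometric(default_params, "anti", n_trials=50_000, seed=11)


@pytest.fixture(scope="session")
def cps_curve(default_params):
    """Model-predicted prosaccade tachometric curve, 5e4 trials."""
    return predicted_tachometric(default_params, "pro", n_trials=50_000, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
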