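import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sowmotion.features import extract_features
from sowmotion.synthetic_data import SimConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_2h():
    """One 2-h simulated sow, reused across tests (read-only)."""
    return simulate(SimConfig(seed=11, duration_h=2.0, animal_id="sow11"))


@pytest.fixture(scope="session")
def sim_2h_frames(sim_2h):
    return extract_features(sim_2h.trace)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
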