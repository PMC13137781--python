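import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctoam.synthetic_patella import SimulationConfig

settings.register_profile(
    "ci", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact phantom: quick to build, still >100 plate pixels per stripe."""
    return SimulationConfig(n_patients=3, volume_shape=(32, 24, 40), seed=7)


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    return SimulationConfig(n_patients=2, volume_shape=(32, 24, 40),
                            noise_sd_hu=0.0, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
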