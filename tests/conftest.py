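import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from olfactomap.config import SimConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Scaled-down simulation for unit tests (full defaults are exercised
    by the acceptance suite)."""
    return SimConfig(
        seed=7,
        fov_px=48,
        um_per_px=48.0,
        odorants=("L", "H"),
        n_trials=3,
        noise_sd=0.01,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
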