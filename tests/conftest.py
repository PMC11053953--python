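import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pulsemap as pm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_geometry():
    return pm.SceneGeometry(height=80, width=80)


@pytest.fixture(scope="session")
def sinusoid_clip(default_geometry):
    """Noiseless quantized clip at 1.25 Hz (period = exactly 24 samples)."""
    model = pm.SyntheticSkinModel(pulse_frequency_hz=1.25, noise_sd=0.0)
    return pm.generate_synthetic_clip(model, default_geometry, 120, 30.0, seed=0)


@pytest.fixture(scope="session")
def noisy_clip(default_geometry):
    """Default noise regime, chin stand present, 1.4 Hz."""
    geo = pm.SceneGeometry(height=80, width=80, chin_stand=True)
    model = pm.SyntheticSkinModel(pulse_frequency_hz=1.4, noise_sd=1.0)
    return pm.generate_synthetic_clip(model, geo, 120, 30.0, seed=2)


class FakeRng:
    """Deterministic stand-in for numpy Generator in augmentation tests."""

    def __init__(self, k: int, uniform_value: float = 1.0):
        self.k = k
        self.uniform_value = uniform_value

    def integers(self, low, high=None):
        return self.k

    def random(self, shape=None):
        if shape is None:
            return self.uniform_value
        return np.full(shape, self.uniform_value)


@pytest.fixture
def fake_rng_factory():
    return FakeRng
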