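import numpy as np
import pytest

from blinkkit.camera import CameraModel


@pytest.fixture
def fast_camera():
    """2-ms exposure / 3-ms cycle acquisition (on-time measurements)."""
    return CameraModel(pixel_size=100.0, exposure=0.002, cycle=0.003,
                       quantum_efficiency=0.9, read_noise=1.0,
                       offset=100.0, conversion=0.5)


@pytest.fixture
def slow_camera():
    """25-ms exposure / 27-ms cycle acquisition (off-time measurements)."""
    return CameraModel(pixel_size=100.0, exposure=0.025, cycle=0.027,
                       quantum_efficiency=0.9, read_noise=1.0,
                       offset=100.0, conversion=0.5)


@pytest.fixture
def clean_camera():
    """Noise-free unit-gain camera for deterministic oracle checks."""
    return CameraModel(pixel_size=100.0, exposure=0.01, cycle=0.01,
                       quantum_efficiency=1.0, read_noise=0.0,
                       offset=100.0, conversion=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
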