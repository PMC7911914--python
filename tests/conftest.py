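import numpy as np
import pytest

from speedkin import CameraModel, OpticsModel, SimScene


@pytest.fixture
def camera():
    """Default EMCCD model (107 nm pixels, 2 ms frames, gain 300)."""
    return CameraModel()


@pytest.fixture
def quiet_camera():
    """Noiseless unit-gain camera: counts equal photons exactly in the mean."""
    return CameraModel(em_gain=1, read_noise_e=0.0, offset_adu=0.0,
                       electrons_per_adu=1.0)


@pytest.fixture
def optics():
    return OpticsModel()


@pytest.fixture
def scene():
    return SimScene()
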