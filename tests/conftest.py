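import numpy as np
import pytest

from retidend import stimuli, synthetic


@pytest.fixture(scope="session")
def noise_stim():
    """Short dense-noise presentation shared across tests."""
    return stimuli.gen_dense_noise(20, 15, 30.0, 5.0, 60.0, seed=42)


@pytest.fixture(scope="session")
def recording(noise_stim):
    """Synthetic two-ROI recording with modest noise."""
    return synthetic.gen_recording(noise_stim, n_rois=2, noise_sd=0.05,
                                  seed=7)


@pytest.fixture(scope="session")
def clean_recording(noise_stim):
    """Noise- and drift-free recording (pixels of one ROI identical)."""
    return synthetic.gen_recording(noise_stim, n_rois=2, noise_sd=0.0,
                                  drift_amp=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
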