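import numpy as np
import pytest

from rewardkit.config import SimulationConfig
from rewardkit.simulate import make_roi_mask, make_signature_map


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def config():
    """Paper-scale configuration (4 subjects x 12 sessions)."""
    return SimulationConfig(seed=11)


@pytest.fixture
def small_config():
    """Desk-scale configuration on a small lattice."""
    return SimulationConfig(seed=11, n_subjects=2, n_sessions=4,
                            grid_shape=(6, 6, 6))


@pytest.fixture
def noiseless_config():
    """All stochastic components switched off: pure mean structure."""
    return SimulationConfig(
        seed=11, grid_shape=(6, 6, 6),
        sigma2_subject=0.0, sigma2_session=0.0, sigma2_trial=0.0,
        gamma_mood=0.0, gamma_alert=0.0, delta_induction=0.0,
        mood_subject_sd=0.0, mood_noise_sd=0.0, kss_noise_sd=0.0,
        panas_noise_sd=0.0, tsnr=np.inf, drift_percent_sd=0.0,
        fd_frame_sd=0.0)


@pytest.fixture
def grid_maps(rng):
    shape = (6, 6, 6)
    roi = make_roi_mask(shape)
    signature = make_signature_map(shape, rng)
    return roi, signature
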