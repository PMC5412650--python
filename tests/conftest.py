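import numpy as np
import pytest

from hemopulse import SimulationConfig, simulate_ground_truth, simulate_recording


@pytest.fixture(scope="session")
def default_session():
    """120 s default simulated session (Mayer wave, HRV, default noise)."""
    cfg = SimulationConfig(duration=120.0, seed=1)
    rec, gt = simulate_recording(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def protocol_session():
    """Breath-hold task: 5 × 30 s holds separated by 30 s rest."""
    cfg = SimulationConfig.breath_hold_protocol(seed=3)
    rec, gt = simulate_recording(cfg)
    return cfg, rec, gt


@pytest.fixture
def quiet_cfg():
    """Noise-free, variability-free degenerate configuration."""
    return SimulationConfig(
        duration=30.0, seed=0, hr_variability_sd=0.0, mayer_amplitude=0.0,
        chest_noise_sd=0.0, neck_noise_sd=0.0, meg_background_sd=0.0,
        nirs_noise_sd=0.0, respiration_amplitude=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
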