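import numpy as np
import pytest

from tacsim import SimulationConfig, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast session layout for structural tests."""
    return SimulationConfig(
        n_subjects=2, srate=250.0, n_blocks=2, trials_per_block=6,
        rest_dur=12.0, break_dur=0.5, env_sigma=0.1, noise_amp=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_config):
    return simulate_subject(tiny_config, 0, np.random.default_rng(99))


@pytest.fixture(scope="session")
def suppression_config():
    """Low-noise configuration with a strong known suppression effect."""
    return SimulationConfig(
        n_subjects=1, srate=250.0, n_blocks=4, trials_per_block=26,
        rest_dur=2.0, break_dur=0.5, suppression_depth=0.3,
        suppression_tau=150.0, env_sigma=0.05, noise_amp=6.0,
        alpha_amp_ec=20.0, alpha_amp_eo=15.0, noise_spatial_r=0.7,
    )
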