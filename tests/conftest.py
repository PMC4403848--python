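import numpy as np
import pytest

from tugseg import SimulationParams, default_config, simulate_tug


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def sim_trial():
    """One default-noise 10 m trial with ground truth (fixed seed)."""
    return simulate_tug(SimulationParams(seed=42))


@pytest.fixture(scope="session")
def noise_free_trial():
    """A clean trial: no noise, no drift — the detection sanity oracle."""
    return simulate_tug(
        SimulationParams(seed=0, noise_sd=0.0, drift_slope=0.0, quat_noise_rad=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
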