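import numpy as np
import pytest

from longidesign import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """One-cell study: 20 participants, 5 sessions, single bundle/measure."""
    return SimulationConfig(bundles=("CC3",), measures=("MD",), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def noisefree_config():
    """Deterministic study: no residual noise, no jitter, no slope spread."""
    return SimulationConfig(
        bundles=("CC3",), measures=("MD",), jitter_days=0.0,
        noise_sd=0.0, slope_sd=0.0, intercept_sd=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
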