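"""Shared fixtures: small, fast synthetic sessions and epoch sets."""

import numpy as np
import pytest

from conveegnn import SimConfig, simulate_epochs, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A 12-trial raw session with blinks and drift, default montage."""
    return simulate_session(SimConfig(n_trials=12, seed=42))


@pytest.fixture(scope="session")
def clean_session():
    """A 10-trial session with no blinks and no drift trials."""
    return simulate_session(
        SimConfig(n_trials=10, blink_rate=0.0, drift_trial_fraction=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def small_epochs():
    """20 directly simulated epochs (30 channels, 1500 samples)."""
    return simulate_epochs(SimConfig(n_trials=20, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
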