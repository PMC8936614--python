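"""Shared fixtures: small seeded synthetic datasets reused across modules."""

import numpy as np
import pytest

from actisense.synthdata import SimConfig, TrueDDMParams, generate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """2 participants x 3 conditions x 4 amplitudes x 4 trials, 5 channels."""
    return SimConfig(
        n_participants=2, n_trials_per_cell=4, n_channels=5, fs=50.0,
        amplitude_levels=[0.75, 0.9, 1.1, 1.25], seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def behavior_cfg() -> SimConfig:
    """Single-condition behavior-only config for decision-model tests."""
    return SimConfig(
        n_participants=4, n_trials_per_cell=8, conditions=["VH"],
        coupling_snr={"VH": 1.0},
        amplitude_levels=[0.75, 0.9, 1.1, 1.25],
        true_ddm=TrueDDMParams(gamma0=0.8, gamma1={"VH": 2.0}, alpha=2.0),
        seed=314)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
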