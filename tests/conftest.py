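"""Shared fixtures: phantom configs and pipeline runs reused across tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from cdtikit.phantom import PhantomConfig, build_truth, generate_study
from cdtikit.pipeline import run_single_study


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def quiet_config() -> PhantomConfig:
    """Default protocol with noise, shifts and corruption switched off."""
    return dataclasses.replace(
        PhantomConfig(), noise_sigma=0.0, shift_sd=0.0, corrupt_prob=0.0
    )


@pytest.fixture(scope="session")
def small_quiet_config() -> PhantomConfig:
    """Tiny noiseless single-slice phantom for cheap exact checks."""
    return dataclasses.replace(
        PhantomConfig(),
        grid_size=32,
        n_slices=1,
        n_repetitions=1,
        noise_sigma=0.0,
        shift_sd=0.0,
        corrupt_prob=0.0,
    )


@pytest.fixture(scope="session")
def quiet_truth(quiet_config):
    return build_truth(quiet_config)


@pytest.fixture(scope="session")
def quiet_study(quiet_config):
    return generate_study(quiet_config)


@pytest.fixture(scope="session")
def quiet_result(quiet_config):
    return run_single_study(quiet_config)


@pytest.fixture(scope="session")
def noisy_result(default_config):
    return run_single_study(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20120)
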