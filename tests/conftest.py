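"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from sarprobit import McmcConfig, SimConfig, run_sampler, simulate_dataset


@pytest.fixture(scope="session")
def study_sim():
    """A study-condition dataset (n=242, defaults)."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """A small dataset for fast sampler/effects tests."""
    return simulate_dataset(SimConfig(n=60, rho_true=0.3, seed=11))


@pytest.fixture(scope="session")
def small_posterior(small_sim):
    """A short SAR chain on the small dataset."""
    return run_sampler(
        small_sim.table,
        small_sim.w,
        cfg=McmcConfig(n_draws=800, burn_in=200, seed=4),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
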