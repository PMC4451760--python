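"""Shared fixtures: populations are built once per session (the N=50 Gabor
filter bank is the expensive one) and never mutated by tests."""

import numpy as np
import pytest

import fisherinfo as fi

THETA_PLUS, THETA_MINUS = 0.0, -7.0


@pytest.fixture(scope="session")
def gabor50():
    return fi.build_filter_bank(N=50, gain=30.0, seed=0)


@pytest.fixture(scope="session")
def gabor50_truth(gabor50):
    return gabor50.ground_truth(THETA_PLUS, THETA_MINUS)


@pytest.fixture(scope="session")
def gabor10():
    return fi.build_filter_bank(N=10, gain=30.0, seed=0)


@pytest.fixture(scope="session")
def gauss20():
    """Correlated Gaussian oracle population, known information I = 5."""
    return fi.GaussianPopulation.random(20, info=5.0, dtheta=0.1, seed=3)


@pytest.fixture(scope="session")
def gauss_diag():
    """Independent (diagonal-covariance) Gaussian population."""
    return fi.GaussianPopulation.random(12, info=4.0, dtheta=0.5, seed=5,
                                        correlated=False)


@pytest.fixture()
def small_trials():
    """A tiny deterministic TrialSet for interface tests."""
    rng = np.random.default_rng(7)
    return fi.TrialSet(rng.poisson(8.0, (30, 4)).astype(float),
                       rng.poisson(6.0, (30, 4)).astype(float), dtheta=2.0)
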