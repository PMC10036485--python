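"""Shared fixtures: small synthetic datasets and hand-built stub models."""

import numpy as np
import pytest

from emgintent import SimConfig, simulate_dataset
from emgintent.gmm_hmm import FitOptions, HmmModel, StateEmission
from emgintent.hierarchy import train_conventional, train_hierarchical


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(trials_per_condition=6, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, n_subjects=1)


@pytest.fixture(scope="session")
def light_opts() -> FitOptions:
    return FitOptions(max_iter=12, n_init=1, rel_tol=1e-3, seed=0)


@pytest.fixture(scope="session")
def trained_hierarchical(small_dataset, light_opts):
    return train_hierarchical(small_dataset, light_opts)


@pytest.fixture(scope="session")
def trained_conventional(small_dataset, light_opts):
    return train_conventional(small_dataset, light_opts)


def make_random_model(n_states: int, n_mix: int, dim: int,
                      rng: np.random.Generator) -> HmmModel:
    """A fully random ergodic GMM-HMM (test oracle input)."""
    pi = rng.dirichlet(np.ones(n_states))
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    emissions = []
    for _ in range(n_states):
        weights = rng.dirichlet(np.ones(n_mix))
        means = rng.normal(0.0, 2.0, size=(n_mix, dim))
        covs = np.array([
            np.eye(dim) * rng.uniform(0.3, 2.0) for _ in range(n_mix)])
        emissions.append(StateEmission(weights, means, covs))
    return HmmModel(n_states=n_states, startprob=pi, transmat=A,
                    emissions=emissions, topology="ergodic")


def single_gaussian_hmm(means, transmat, startprob, var=0.5) -> HmmModel:
    """Left-to-right HMM with one unit-weight Gaussian per state."""
    means = np.atleast_2d(np.asarray(means, float))
    dim = means.shape[1]
    emissions = [StateEmission([1.0], [m], [np.eye(dim) * var])
                 for m in means]
    return HmmModel(n_states=means.shape[0], startprob=startprob,
                    transmat=transmat, emissions=emissions)
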