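"""Shared fixtures.

Two domain scales are used: a tiny 4-hour series for cheap unit tests, and
the coarse 27-hour study series (the conditions under which the synthetic
datasets are generated and the recovery experiments run).  The expensive
session fixtures are built lazily so test files that do not need them stay
fast.
"""

import numpy as np
import pytest

import limbgrn as lg
from limbgrn.solver import SeriesContext


@pytest.fixture(scope="session")
def tiny_series():
    return lg.build_growth_series(n_hours=4, target_edge=90.0)


@pytest.fixture(scope="session")
def coarse_series():
    return lg.build_growth_series(n_hours=27, target_edge=65.0)


@pytest.fixture(scope="session")
def coarse_ctx(coarse_series):
    return SeriesContext(coarse_series)


@pytest.fixture(scope="session")
def truth_trajectory(coarse_series, coarse_ctx):
    return lg.generate_ground_truth(coarse_series, "C", hours=(0, 27),
                                    ctx=coarse_ctx)


@pytest.fixture(scope="session")
def noisy_dataset(truth_trajectory):
    return lg.sample_observations(truth_trajectory, noise_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def noiseless_dataset(truth_trajectory):
    return lg.sample_observations(truth_trajectory, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def selection_table(noisy_dataset, coarse_series):
    """The 27-start model-selection protocol on Models A-D (shared by the
    ranking and robustness acceptance tests)."""
    from limbgrn import protocols
    return protocols.run_selection(noisy_dataset, coarse_series, seed=11)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_dataset, coarse_series):
    """Best-of-27 fit of Model C to noiseless data (parameter recovery)."""
    from limbgrn import protocols
    return protocols.run_recovery(noiseless_dataset, coarse_series, seed=5)
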