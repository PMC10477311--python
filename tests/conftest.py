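"""Shared fixtures: synthetic datasets and one full desk-scale model fit.

The desk-preset fit (30 reserves / 20 remote / 100 fished, 4 chains x 1000+1000) is
session-scoped because several tests interrogate the same posterior; everything is
seeded so the suite is deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from reefmsy import model as M
from reefmsy.simulate import DatasetDesign, desk_design, simulate_dataset

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def desk_table_truth():
    return simulate_dataset(design=desk_design(), seed=1)


@pytest.fixture(scope="session")
def desk_table(desk_table_truth):
    return desk_table_truth[0]


@pytest.fixture(scope="session")
def desk_truth(desk_table_truth):
    return desk_table_truth[1]


@pytest.fixture(scope="session")
def desk_data(desk_table):
    return M.prepare_data(desk_table)


@pytest.fixture(scope="session")
def desk_fit(desk_data):
    """The reference posterior: desk preset, 4 chains, 1000 warmup + 1000 draws."""
    return M.fit(desk_data, n_chains=4, n_warmup=1000, n_samples=1000, seed=1)


@pytest.fixture(scope="session")
def desk_diagnostics(desk_fit):
    return M.diagnostics(desk_fit)


@pytest.fixture()
def tiny_design():
    return DatasetDesign(n_reserve=12, n_remote=8, n_fished=40, n_jurisdictions=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
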