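"""Shared fixtures: solved synthetic worlds and their emitted tables."""

import numpy as np
import pytest

from migraine_states import synthetic


@pytest.fixture(scope="session")
def constant_world():
    """Constant-hazard world (i_gbd = 0.02, r = 0.05) and its solution."""
    truth = synthetic.constant_ground_truth(i=0.02, r=0.05)
    solution = synthetic.solve_truth(truth)
    return truth, solution


@pytest.fixture(scope="session")
def constant_table(constant_world):
    """Noiseless GBD-layout table emitted from the constant world."""
    _, solution = constant_world
    return synthetic.emit_gbd_tables(solution, noise=0.0, seed=0)


@pytest.fixture(scope="session")
def default_world():
    """The package's reference bell-shaped world, solved."""
    truth = synthetic.default_ground_truth(noise=0.0)
    solution = synthetic.solve_truth(truth)
    return truth, solution


@pytest.fixture(scope="session")
def default_table(default_world):
    _, solution = default_world
    return synthetic.emit_gbd_tables(solution, noise=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(321)
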