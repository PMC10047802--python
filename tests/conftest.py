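import numpy as np
import pytest

from fracpde import datagen as dg
from fracpde.grids import SpatialGrid, TrajectoryDataset


@pytest.fixture(scope="session")
def grid1d_small():
    return dg.example2_grid(60)


@pytest.fixture(scope="session")
def grid2d_small():
    return dg.example1_grid(24)


@pytest.fixture(scope="session")
def tiny_ex2_data():
    """Small noiseless 1-D benchmark dataset shared across unit tests."""
    return dg.make_example_dataset(2, 0.0, seed=11, n_init=4, sizes=(2, 1, 1))


@pytest.fixture(scope="session")
def tiny_ex2_noisy():
    return dg.make_example_dataset(2, 0.01, seed=11, n_init=4, sizes=(2, 1, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_constant_dataset(grid, u_vals, v_vals, dt=0.05):
    """Trajectory whose snapshots are prescribed constants (for loss
    bookkeeping checks)."""
    n_time = len(u_vals) - 1
    u = np.stack([np.full(grid.shape, c) for c in u_vals])[None]
    v = np.stack([np.full(grid.shape, c) for c in v_vals])[None]
    return TrajectoryDataset(u, v, grid, dt)
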