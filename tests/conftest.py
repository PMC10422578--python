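import numpy as np
import pytest

from thermotau import build_dataset, make_time_grid


@pytest.fixture(scope="session")
def grid():
    return make_time_grid()


@pytest.fixture(scope="session")
def small_dataset(grid):
    """A small clean corpus shared by read-only tests."""
    return build_dataset(64, grid=grid, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
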