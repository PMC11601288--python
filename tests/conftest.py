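import numpy as np
import pandas as pd
import pytest

from subspot import synthetic
from subspot.grid import ChannelLayout


@pytest.fixture(scope="session")
def sim():
    """The stated simulation world: 20x20 grid, 4 types, 200 genes, depth 2000."""
    return synthetic.simulate_dataset(seed=0)


@pytest.fixture(scope="session")
def truth():
    return synthetic.default_truth(seed=0)


@pytest.fixture(scope="session")
def small_layout():
    return ChannelLayout(n_a=5, n_b=5, channel_width=25.0, pitch=50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def labelled_cells(sim) -> pd.Series:
    return sim.cells.set_index("cell_id")["label"]
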