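import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from benthos import CellEnvelopes, DepthBins, make_world


@pytest.fixture(scope="session")
def world():
    """A mid-sized synthetic world shared by read-only tests."""
    return make_world(seed=11, n_species=80)


@pytest.fixture(scope="session")
def envelopes(world):
    return CellEnvelopes.from_grid(world.bathy)


@pytest.fixture(scope="session")
def strat_bins():
    return DepthBins.stratified()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
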