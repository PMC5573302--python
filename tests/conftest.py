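import numpy as np
import pytest

from oncolattice.config import load_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, fast world: 8^3 lattice, short horizon."""
    return load_config(None, {
        "geometry": {"nx": 8, "ny": 8, "nz": 8},
        "horizon": 5,
        "seed": 7,
    })


@pytest.fixture
def small_world(small_config):
    from oncolattice.agents import initialize_world
    return initialize_world(small_config)
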