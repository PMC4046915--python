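import numpy as np
import pytest

from pepwave import load_builtin, simulate
from pepwave.fixtures import make_toy_network


@pytest.fixture(scope="session")
def ecoli():
    """The shipped calibrated E. coli central-carbon-metabolism network."""
    return load_builtin()


@pytest.fixture(scope="session")
def toy():
    return make_toy_network(n_chain=3, branch=False, seed=7)


@pytest.fixture(scope="session")
def toy_branched():
    return make_toy_network(n_chain=3, branch=True, seed=11)


@pytest.fixture(scope="session")
def baseline_traj(ecoli):
    """Unforced 8 h run on a 60 s reporting grid (also warms the kernels)."""
    return simulate(ecoli, None, grid_dt=60.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140605)
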