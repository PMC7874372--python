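import numpy as np
import pytest

from dmn_subsys.rois import RoiSet
from dmn_subsys.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def roiset():
    return RoiSet.default()


@pytest.fixture(scope="session")
def partition(roiset):
    return roiset.partition()


@pytest.fixture
def small_config():
    return SimulationConfig(n_per_group=10, T=120, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_symmetric(rng, n=11, signed=True):
    a = rng.normal(size=(n, n))
    w = (a + a.T) / 2.0
    if not signed:
        w = np.abs(w)
    np.fill_diagonal(w, 0.0)
    return w
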