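import numpy as np
import pytest

from laminarbold.physio import CalibParams
from laminarbold.synth import make_protocol, make_slab


@pytest.fixture(scope="session")
def params():
    return CalibParams()


@pytest.fixture(scope="session")
def protocol():
    return make_protocol()


@pytest.fixture(scope="session")
def small_slab():
    """A 10x10x22 slab: 1800 analysed voxels, fast enough for per-test use."""
    return make_slab((10, 10, 22))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
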