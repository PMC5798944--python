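import numpy as np
import pytest

from chromotune import default_topology


@pytest.fixture(scope="session")
def topo():
    return default_topology()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
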