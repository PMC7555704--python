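import numpy as np
import pytest

from pyrscat import load_builtin
from pyrscat.transport import Physics


@pytest.fixture(scope="session")
def dataset():
    return load_builtin("recommended")


@pytest.fixture(scope="session")
def smc_dataset():
    return load_builtin("smc")


@pytest.fixture(scope="session")
def physics(dataset):
    return Physics.default(dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
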