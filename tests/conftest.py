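import numpy as np
import pytest
from hypothesis import settings

from oligokin.params import DEFAULT_NN
from oligokin.strands import RnaStrand

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def nn():
    return DEFAULT_NN


@pytest.fixture
def octamer():
    a = RnaStrand("a", "ACGUACGU")
    return a, a.reverse_complement("b")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
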