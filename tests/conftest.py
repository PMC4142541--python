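import numpy as np
import pytest

from glomsim.receptor import build_preset


@pytest.fixture(scope="session")
def alpha1():
    return build_preset("alpha1")


@pytest.fixture(scope="session")
def alpha6():
    return build_preset("alpha6")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
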