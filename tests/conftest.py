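import numpy as np
import pytest

from vestsim.params import load_variant


@pytest.fixture(scope="session")
def original_variant():
    return load_variant("original_hk")


@pytest.fixture(scope="session")
def invivo_variant():
    return load_variant("invivo")


@pytest.fixture(scope="session")
def invitro_variant():
    return load_variant("invitro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
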