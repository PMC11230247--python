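import numpy as np
import pytest

from fetalfold.surface import build_patches, icosphere


@pytest.fixture(scope="session")
def ico3():
    return icosphere(3)


@pytest.fixture(scope="session")
def ico4():
    return icosphere(4)


@pytest.fixture(scope="session")
def patches3(ico3):
    return build_patches(ico3, 5)


@pytest.fixture(scope="session")
def patches4(ico4):
    return build_patches(ico4, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)
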