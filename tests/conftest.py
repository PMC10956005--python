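import numpy as np
import pytest

from duodomain import synthlab as sl
from duodomain.operators import TransformSpec


@pytest.fixture(scope="session")
def phantom64():
    return sl.make_phantom((64, 64), n_ellipses=5, seed=0)


@pytest.fixture(scope="session")
def phantom32():
    return sl.make_phantom((32, 32), n_ellipses=4, seed=1)


@pytest.fixture(scope="session")
def radon64():
    return TransformSpec("radon", (64, 64), n_angles=90)


@pytest.fixture(scope="session")
def radon32():
    return TransformSpec("radon", (32, 32), n_angles=48)


@pytest.fixture(scope="session")
def fourier64():
    return TransformSpec("fourier", (64, 64))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
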