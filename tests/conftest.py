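import numpy as np
import pytest

from tvdmreg import Image2D, make_phantom


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(64, 64, n_shapes=8, seed=7)


@pytest.fixture(scope="session")
def phantom128():
    return make_phantom(128, 128, n_shapes=12, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_image(rng):
    return Image2D(rng.normal(0.0, 1.0, size=(32, 32)))
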