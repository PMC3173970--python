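import numpy as np
import pytest

from mraseg import Image2D, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def phantom_128():
    """Noise-free phantom at the native 128×128 / 4.6875 mm resolution."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_512_spec():
    return PhantomSpec(grid=(512, 512), pixel_size_mm=4.6875 / 4.0)


@pytest.fixture(scope="session")
def phantom_512(phantom_512_spec):
    """Noise-free phantom rendered four times finer (512×512 / ~1.17 mm)."""
    return generate_phantom(phantom_512_spec)


@pytest.fixture
def random_image(rng):
    def make(m, n=None, pixel_size_mm=1.0):
        n = m if n is None else n
        return Image2D(rng.normal(size=(m, n)), pixel_size_mm=pixel_size_mm)

    return make
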