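import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_coil_images(rng):
    """Random complex 3-coil 8x8 image stack."""
    return rng.standard_normal((3, 8, 8)) + 1j * rng.standard_normal((3, 8, 8))
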