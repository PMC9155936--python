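import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Factory for seeded random images on the 0-255 scale."""

    def make(shape=(16, 16), seed=None):
        gen = np.random.default_rng(seed) if seed is not None else rng
        return gen.uniform(0.0, 255.0, size=shape)

    return make
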