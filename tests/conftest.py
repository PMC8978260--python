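import numpy as np
import pytest

from morphseg.phantom import PhantomConfig, generate_phantom
from morphseg.volume import BinaryMask, Volume


@pytest.fixture(scope="session")
def phantom32():
    """One deterministic 32^3 phantom shared across tests."""
    return generate_phantom(PhantomConfig(shape=(32, 32, 32), seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_volume():
    g = np.arange(4 * 4 * 4, dtype=np.float32).reshape(4, 4, 4)
    return Volume(g, spacing=(1.0, 1.0, 0.5))


def random_mask(rng, shape=(16, 16, 16), p=0.3) -> BinaryMask:
    return BinaryMask((rng.random(shape) < p).astype(np.uint8))
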