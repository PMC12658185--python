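import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantoms():
    """Tiny balanced phantom set shared across tests (8 per class, 64 px)."""
    from lightmg.synthetic import generate_dataset

    images, labels, manifest = generate_dataset(8, size=64, seed=99)
    return images, np.asarray(labels), manifest
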