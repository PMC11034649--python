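import numpy as np
import pytest

from plmt.backbone import ArchSpec


@pytest.fixture(scope="session")
def tiny_arch():
    """Smallest architecture that still exercises skip connections."""
    return ArchSpec(in_channels=1, num_classes=2, base_channels=4, depth=2)


@pytest.fixture(scope="session")
def tri_arch():
    return ArchSpec(in_channels=1, num_classes=4, base_channels=4, depth=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(16, 16), p=0.3):
    return rng.random(shape) < p
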