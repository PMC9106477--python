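import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_masks(rng):
    """200 random 16x16 binary masks at varying densities."""
    masks = []
    for i in range(200):
        p = 0.15 + 0.7 * (i % 10) / 9.0
        masks.append(rng.random((16, 16)) < p)
    return masks


@pytest.fixture
def exhaustive_small_masks():
    """All 512 3x3 patterns embedded centrally in a 6x6 frame."""
    masks = []
    for bits in range(512):
        patch = np.array([(bits >> k) & 1 for k in range(9)],
                         dtype=bool).reshape(3, 3)
        frame = np.zeros((6, 6), dtype=bool)
        frame[1:4, 2:5] = patch
        masks.append(frame)
    return masks
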