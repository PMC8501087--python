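import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_mask_pair(rng, max_size=32, p=0.35, nonempty=True):
    """A random (pred, ref) mask pair with at least one fg pixel each."""
    h = int(rng.integers(4, max_size + 1))
    w = int(rng.integers(4, max_size + 1))
    while True:
        pred = (rng.random((h, w)) < p).astype(np.uint8)
        ref = (rng.random((h, w)) < p).astype(np.uint8)
        if not nonempty or (pred.any() and ref.any()):
            return pred, ref
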