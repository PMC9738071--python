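import numpy as np
import pytest

from periocort import RadiographImage


@pytest.fixture
def rng():
    return np.random.default_rng(20220712)


@pytest.fixture
def random_image(rng):
    """A 40x60 8-bit image with full-range random texture."""
    return RadiographImage(
        pixels=rng.integers(0, 256, (40, 60), dtype=np.uint8).astype(np.int64),
        bit_depth=8,
        image_id="random",
    )


def full_roi(shape):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.column_stack([rr.ravel(), cc.ravel()])
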