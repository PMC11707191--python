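import numpy as np
import pytest

from leadassay.imaging import RGBImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def solid_rgb(shape, r, g, b) -> RGBImage:
    """Uniform colour image helper used across test modules."""
    return RGBImage(
        np.full(shape, float(r)),
        np.full(shape, float(g)),
        np.full(shape, float(b)),
    )
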