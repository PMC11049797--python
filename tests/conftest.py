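import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240322)


@pytest.fixture
def small_rgb():
    """A deterministic 12x16 8-bit RGB image with mid-range values."""
    from beecolor.image_io import RGBImage

    g = np.random.default_rng(7)
    px = g.integers(20, 220, size=(12, 16, 3), dtype=np.uint8)
    return RGBImage(pixels=px, bit_depth=8, image_id="fixture")
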