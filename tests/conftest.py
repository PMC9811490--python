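import numpy as np
import pytest

from hemipact.geometry import build_array


@pytest.fixture(scope="session")
def default_geom():
    """The published array: 1024 elements, R = 60 mm, 12 mm^2, cap 63.6 deg."""
    return build_array()


@pytest.fixture(scope="session")
def small_geom():
    """Reduced 64-element array for fast forward/inverse tests (element
    area scaled to keep the aperture coverage of the published layout)."""
    return build_array(n_elements=64, element_area_mm2=12.0 * 1024 / 64)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
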