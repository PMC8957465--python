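import numpy as np
import pytest

from arthromri.cohort import default_cohort_spec, make_cohort
from arthromri.phantom import default_phantom_spec, make_phantom


@pytest.fixture(scope="session")
def default_cohort():
    return make_cohort(default_cohort_spec(seed=7))


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(default_phantom_spec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def disk_image():
    """Noiseless filled disk, radius 20, centered in a 64x64 raster."""
    img = np.zeros((64, 64))
    rr, cc = np.ogrid[:64, :64]
    img[(rr - 32) ** 2 + (cc - 32) ** 2 <= 400] = 200.0
    return img
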