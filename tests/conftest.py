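import numpy as np
import pytest

from nethom.core import BrainMask, TimeSeriesImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_image(rng, shape=(6, 6, 6), n_volumes=60, tr=2.0, voxel_mm=3.0):
    data = rng.standard_normal(shape + (n_volumes,))
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return TimeSeriesImage(data, affine, tr)


def make_mask(shape=(6, 6, 6), voxel_mm=3.0, fill=True):
    m = np.zeros(shape, dtype=bool)
    if fill:
        m[:] = True
    return BrainMask(m, np.diag([voxel_mm] * 3 + [1.0]))


@pytest.fixture
def image_factory():
    return make_image


@pytest.fixture
def mask_factory():
    return make_mask
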