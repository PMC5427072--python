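import numpy as np
import pytest

from restingstop import VolumeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(data, mask=None, tr_s=2.0, voxel_mm=2.0):
    """VolumeSeries with an isotropic affine; mask defaults to all-true."""
    data = np.asarray(data)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return VolumeSeries(data=data, mask=mask, affine=affine, tr_s=tr_s)


@pytest.fixture
def series_factory():
    return make_series
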