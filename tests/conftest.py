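import numpy as np
import pytest

from xaibench3d.core import Sample3D
from xaibench3d.fixtures import (
    LinearAdapter,
    TinyAttentionAdapter,
    TinyConvAdapter,
    TinyPointAdapter,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def volume_sample(rng):
    return Sample3D("vol-0", "volumetric", rng.standard_normal((16, 16, 16)) * 0.5,
                    true_label=0, predicted_label=1)


@pytest.fixture
def voxel_sample(rng):
    occ = (rng.uniform(size=(16, 16, 16)) < 0.2).astype(float)
    occ.flat[0] = 1.0  # guarantee non-empty occupancy
    return Sample3D("vox-0", "voxel", occ, true_label=1, predicted_label=1)


@pytest.fixture
def point_sample(rng):
    return Sample3D("pts-0", "pointcloud", rng.standard_normal((64, 3)) * 0.4,
                    true_label=2, predicted_label=0)


@pytest.fixture
def conv_adapter():
    return TinyConvAdapter(input_shape=(16, 16, 16), n_classes=3, seed=1)


@pytest.fixture
def attention_adapter():
    return TinyAttentionAdapter(input_shape=(16, 16, 16), n_classes=3, seed=2)


@pytest.fixture
def point_adapter():
    return TinyPointAdapter(n_classes=3, seed=3)


def make_linear_grid(weights_flat):
    """Linear oracle adapter over a (1, 1, n) grid plus the matching sample."""
    w = np.asarray(weights_flat, dtype=float).reshape(1, 1, -1)
    return LinearAdapter(w)
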