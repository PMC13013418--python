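import numpy as np
import pytest

from nhocrad.imgvol import BinaryMask, ScalarVolume, VolumeGeometry


@pytest.fixture
def geom_1mm():
    return VolumeGeometry(shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_volume(values, spacing=(1.0, 1.0, 1.0), modality="PET", origin=(0.0, 0.0, 0.0)):
    values = np.asarray(values, float)
    geom = VolumeGeometry(shape=values.shape, spacing=spacing, origin=origin)
    return ScalarVolume(geometry=geom, values=values, modality=modality)


def make_mask(values, spacing=(1.0, 1.0, 1.0), label="m", origin=(0.0, 0.0, 0.0)):
    values = np.asarray(values)
    geom = VolumeGeometry(shape=values.shape, spacing=spacing, origin=origin)
    return BinaryMask(geometry=geom, values=values, label=label)


def sphere_mask_array(shape, centre, radius, spacing=(1.0, 1.0, 1.0)):
    """Voxel-centre sphere indicator on a grid (node-centred convention)."""
    idx = np.indices(shape)
    d2 = sum(((idx[a] * spacing[a] - centre[a]) ** 2) for a in range(3))
    return d2 <= radius**2


def simulate_survival(rng, n, lp, base_scale=600.0, censor_max=2000.0):
    """Exponential PH survival with uniform censoring; returns (time, event)."""
    t = rng.exponential(base_scale * np.exp(-np.asarray(lp)))
    c = rng.uniform(0, censor_max, n)
    time = np.maximum(np.minimum(t, c), 1.0)
    event = (t <= c).astype(int)
    return time, event
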