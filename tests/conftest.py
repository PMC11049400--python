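import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dceradiomics.io_core import DynamicSeries, ImageVolume, RoiMask

settings.register_profile(
    "ci", max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_volume(shape=(4, 4, 4), value=0.0, spacing=(1.0, 1.0, 1.0), dtype=float):
    return ImageVolume(voxels=np.full(shape, value, dtype=dtype), spacing=spacing)


def make_series(n=7, shape=(4, 4, 4), spacing=(1.0, 1.0, 1.0), values=None,
                modality="CT"):
    """A constant-geometry series; values[i] fills volume i (default i)."""
    vols = []
    for i in range(n):
        v = values[i] if values is not None else float(i)
        vols.append(ImageVolume(voxels=np.full(shape, v, float), spacing=spacing))
    return DynamicSeries(volumes=vols, acquisition_times=np.arange(n, dtype=float),
                         modality=modality)


def corner_mask(shape=(4, 4, 4), n=10, label="tumor", spacing=(1.0, 1.0, 1.0)):
    vox = np.zeros(shape, dtype=bool)
    vox.ravel()[:n] = True
    return RoiMask(voxels=vox, label=label, spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
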