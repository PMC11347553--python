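import numpy as np
import pytest

from deltarad.discretize import DiscretizedRoi
from deltarad.imaging import ImageVolume, RoiMask


def droi_from_array(arr) -> DiscretizedRoi:
    """Wrap an integer level array (0 = outside mask) as a DiscretizedRoi."""
    arr = np.asarray(arr, dtype=np.int32)
    return DiscretizedRoi(levels=arr, Ng=int(arr.max()), bin_width=50.0, min_intensity=0.0)


def random_droi(rng: np.random.Generator, max_side: int = 6, max_levels: int = 5) -> DiscretizedRoi:
    """Random small discretized ROI: random shape <= max_side^3, random
    mask coverage, levels 1..max_levels (at least one voxel in-mask)."""
    shape = tuple(rng.integers(1, max_side + 1, size=3))
    levels = rng.integers(0, max_levels + 1, size=shape).astype(np.int32)
    if (levels > 0).sum() == 0:
        levels[tuple(rng.integers(0, s) for s in shape)] = rng.integers(1, max_levels + 1)
    # renumber so the top level is occupied
    return droi_from_array(levels)


def ball_mask(radius_mm: float, spacing=(1.0, 1.0, 1.0), pad: int = 2) -> RoiMask:
    """Digitized ball of the given physical radius."""
    half = [int(np.ceil(radius_mm / s)) + pad for s in spacing]
    shape = [2 * h + 1 for h in half]
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    r2 = sum(((g - h) * s) ** 2 for g, h, s in zip(grids, half, spacing))
    return RoiMask(r2 <= radius_mm**2, tuple(spacing))


def constant_volume(shape, value, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(np.full(shape, float(value)), tuple(spacing))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240826)
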