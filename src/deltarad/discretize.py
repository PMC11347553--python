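"""Gray-level discretization and gradient-magnitude images.

Fixed-bin-width discretization (default width 50, matching ADC maps in
10^-6 mm^2/s) anchored at the ROI minimum::

    level(v) = floor((v - min_roi) / bin_width) + 1

Levels are 1-based inside the mask and 0 outside.  ``Ng`` is the highest
assigned level; with width-based binning interior levels may be empty
(gaps), which the texture-matrix builders handle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateAxisError, EmptyRoiError
from .imaging import ImageVolume, RoiMask, check_geometry


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed-bin-width discretization settings.

    bin_width is in the intensity units of the image (for ADC maps,
    10^-6 mm^2/s; the default of 50 is the standard fixed bin size for
    such maps).  The anchor is always the minimum in-mask intensity.
    """

    bin_width: float = 50.0

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ConfigError(f"bin_width must be positive, got {self.bin_width}")


@dataclass(frozen=True)
class DiscretizedRoi:
    """Integer gray levels on the grid: 0 outside the mask, 1..Ng inside."""

    levels: np.ndarray
    Ng: int
    bin_width: float
    min_intensity: float

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        inside = lv[lv > 0]
        if inside.size == 0:
            raise EmptyRoiError("discretized ROI has no in-mask voxel")
        if inside.max() != self.Ng:
            raise ValueError("Ng must be the highest assigned level")
        object.__setattr__(self, "levels", lv.astype(np.int32))

    @property
    def voxel_count(self) -> int:
        return int((self.levels > 0).sum())


def discretize(volume: ImageVolume, mask: RoiMask, cfg: DiscretizationConfig | None = None) -> DiscretizedRoi:
    """Discretize the masked intensities with a fixed bin width.

    level(v) = floor((v - min)/W) + 1, so the ROI minimum maps to level 1
    and the maximum to floor((max - min)/W) + 1 = Ng.
    """
    cfg = cfg or DiscretizationConfig()
    check_geometry(volume, mask)
    flags = mask.flags
    vals = volume.voxels[flags]
    vmin = float(vals.min())
    levels = np.zeros(volume.shape, dtype=np.int32)
    levels[flags] = np.floor((vals - vmin) / cfg.bin_width).astype(np.int32) + 1
    return DiscretizedRoi(levels=levels, Ng=int(levels.max()), bin_width=cfg.bin_width, min_intensity=vmin)


def gradient_magnitude(volume: ImageVolume) -> ImageVolume:
    """Spacing-aware gradient-magnitude image.

    Central differences in physical units on the interior, one-sided at
    the borders; the result is sqrt(Gx^2 + Gy^2 + Gz^2) on the full grid.
    Computing on the full grid (rather than a mask crop) avoids stencil
    artifacts at the ROI edge.
    """
    if min(volume.shape) < 2:
        raise DegenerateAxisError(f"gradient needs >= 2 voxels per axis, got shape {volume.shape}")
    gx, gy, gz = np.gradient(volume.voxels, *volume.spacing)
    mag = np.sqrt(gx * gx + gy * gy + gz * gz)
    return ImageVolume(mag, volume.spacing, volume.origin)
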