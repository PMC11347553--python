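"""Volume and ROI-mask handling.

Volumes are 3D scalar grids with physical voxel spacing — in this package
typically apparent diffusion coefficient (ADC) maps in units of
10^-6 mm^2/s, or gradient-magnitude images derived from them.  Masks are
binary tumor segmentations on the same grid.  NIfTI-1 is the on-disk
format; :mod:`nibabel` does the reading and writing.

Conventions
-----------
* Voxel indices are 0-based; physical position = origin + index * spacing.
* ROI extraction walks the grid in row-major (z, y, x) order so that the
  intensity list — and every entropy-type feature downstream — is
  deterministic.
* Any nonzero mask value counts as foreground (segmentation exports vary);
  a warning is logged when values outside {0, 1} are present.
* Spacing/origin differences between a volume and its mask above 1e-3 mm
  are geometry errors; smaller differences (header round-off) warn only.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, EmptyRoiError, GeometryError

logger = logging.getLogger(__name__)

#: spacing / origin agreement required between a volume and its mask [mm]
GEOMETRY_TOL_MM = 1e-3


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar values; must be finite.
    spacing : tuple of float
        Voxel spacing (sx, sy, sz) in mm, strictly positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 3:
            raise DimensionalityError(f"expected a 3D volume, got {v.ndim}D")
        if min(v.shape) < 1:
            raise DimensionalityError("every axis must have >= 1 voxel")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel values must be finite")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class RoiMask:
    """Binary tumor mask on the same grid as its companion volume."""

    flags: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        raw = np.asarray(self.flags)
        if raw.ndim != 3:
            raise DimensionalityError(f"expected a 3D mask, got {raw.ndim}D")
        vals = np.unique(raw).astype(np.float64)
        if not set(np.round(vals, 6)).issubset({0.0, 1.0}):
            logger.warning("mask values %s outside {0,1}; treating nonzero as foreground", vals[:5])
        flags = raw != 0
        if not flags.any():
            raise EmptyRoiError("mask has no foreground voxel")
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    @property
    def voxel_count(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class RoiExtract:
    """Foreground voxel values of a volume, in (z, y, x) row-major scan order."""

    intensities: np.ndarray
    voxel_count: int
    bounding_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        vals = np.asarray(self.intensities, dtype=np.float64)
        if vals.shape != (self.voxel_count,):
            raise ValueError("intensities length must equal voxel_count")
        object.__setattr__(self, "intensities", vals)


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a 3D NIfTI scalar image.

    Spacing comes from the header zooms; voxel values are returned
    unmodified (as float64).

    Raises
    ------
    FileNotFoundError
        If `path` does not exist.
    DimensionalityError
        If the image is not 3D (trailing singleton 4th dimensions are
        squeezed first, as scanners commonly emit them).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin)


def read_mask(path: str | os.PathLike) -> RoiMask:
    """Read a binary ROI mask from NIfTI (nonzero = foreground)."""
    vol = read_volume(path)
    return RoiMask(vol.voxels, vol.spacing, vol.origin)


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as float32 NIfTI-1."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine_from(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: RoiMask, path: str | os.PathLike) -> None:
    """Write a mask as uint8 NIfTI-1."""
    img = nib.Nifti1Image(mask.flags.astype(np.uint8), _affine_from(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def check_geometry(volume: ImageVolume, mask: RoiMask) -> None:
    """Validate that `mask` lives on the grid of `volume`.

    Shape must match exactly.  Spacing/origin may differ by at most
    ``GEOMETRY_TOL_MM``; smaller mismatches warn (header round-off).
    """
    if volume.shape != mask.shape:
        raise GeometryError(f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    dsp = np.abs(np.subtract(volume.spacing, mask.spacing))
    dor = np.abs(np.subtract(volume.origin, mask.origin))
    if dsp.max() > GEOMETRY_TOL_MM or dor.max() > GEOMETRY_TOL_MM:
        raise GeometryError(
            f"spacing/origin mismatch beyond {GEOMETRY_TOL_MM} mm: "
            f"Δspacing={tuple(dsp)}, Δorigin={tuple(dor)}"
        )
    if dsp.max() > 0 or dor.max() > 0:
        logger.warning("sub-tolerance geometry mismatch between volume and mask (header round-off?)")


def apply_roi(volume: ImageVolume, mask: RoiMask) -> RoiExtract:
    """Collect the masked voxel intensities in deterministic scan order.

    The scan order is row-major over (z, y, x): the z index varies slowest,
    x fastest — i.e. the array is transposed to (z, y, x) before raveling.
    """
    check_geometry(volume, mask)
    flags_zyx = np.transpose(mask.flags, (2, 1, 0))
    vox_zyx = np.transpose(volume.voxels, (2, 1, 0))
    intensities = vox_zyx[flags_zyx]
    idx = np.argwhere(mask.flags)
    bbox = tuple((int(idx[:, a].min()), int(idx[:, a].max())) for a in range(3))
    return RoiExtract(intensities=intensities, voxel_count=int(flags_zyx.sum()), bounding_box=bbox)
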