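"""Texture-matrix builders on discretized ROIs.

Five matrix families over the 26-neighborhood system (13 unique 3D
directions), all restricted to in-mask voxels:

* GLCM   — gray-level co-occurrence, symmetric, merged over directions.
* GLRLM  — gray-level run lengths; runs break at mask boundaries.
* GLSZM  — gray-level size zones (26-connected equal-level components).
* GLDZM  — the same zones tabulated by minimum city-block distance to the
  ROI border (border voxels have distance 1; the image edge counts as
  border).
* NGTDM  — per-level summed absolute difference from the mean of the
  in-mask 26-neighborhood.

Counts are merged across directions into a single matrix before feature
computation (the aggregation choice is deterministic and keeps the
brute-force oracles simple); per-direction averaging is not offered.
All builders crop to the mask bounding box internally, so cost scales
with the ROI, not the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedRoi
from .errors import DegenerateMatrixError

#: The 13 unique direction vectors of the 3D 26-neighborhood
#: (one representative per +/- pair, ordered lexicographically).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _crop_levels(droi: DiscretizedRoi) -> np.ndarray:
    lv = droi.levels
    idx = np.argwhere(lv > 0)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return lv[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def _offset_views(arr: np.ndarray, off: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Views (a, b) such that b is `arr` shifted by `off` relative to a."""
    sl_a, sl_b = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized symmetric co-occurrence matrix p(i, j), i, j = 1..Ng."""

    p: np.ndarray
    distance: int
    Ng: int

    def __post_init__(self) -> None:
        s = float(self.p.sum())
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"GLCM must be normalized, sums to {s}")
        if not np.allclose(self.p, self.p.T, atol=1e-12):
            raise ValueError("GLCM must be symmetric")


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts r(i, j): level i, run length j (1-based columns)."""

    counts: np.ndarray
    Nr: int
    Np: int
    n_directions: int = len(DIRECTIONS_13)


@dataclass(frozen=True)
class SizeZoneMatrix:
    """Zone counts z(i, s): level i, zone size s (1-based columns)."""

    counts: np.ndarray
    Nz: int
    Np: int


@dataclass(frozen=True)
class DistanceZoneMatrix:
    """Zone counts z(i, d): level i, zone border distance d (1-based)."""

    counts: np.ndarray
    Nz: int
    Np: int


@dataclass(frozen=True)
class NeighborhoodDifferenceTable:
    """NGTDM columns: s_i (summed |level - neighborhood mean|), n_i (voxels)."""

    s: np.ndarray
    n: np.ndarray
    Ng: int

    @property
    def Nv(self) -> int:
        """Voxels with at least one valid in-mask neighbor."""
        return int(self.n.sum())


def build_glcm(droi: DiscretizedRoi, distance: int = 1) -> GLCMatrix:
    """Co-occurrence counts over the 13 directions at `distance`, both
    orderings (symmetric), merged and normalized.

    Raises
    ------
    DegenerateMatrixError
        If no in-mask voxel pair exists at the given distance (e.g. a
        single isolated voxel).
    """
    if distance < 1:
        raise ValueError("distance must be >= 1 voxel")
    lv = _crop_levels(droi)
    Ng = droi.Ng
    counts = np.zeros((Ng, Ng), dtype=np.int64)
    for d in DIRECTIONS_13:
        off = (d[0] * distance, d[1] * distance, d[2] * distance)
        a, b = _offset_views(lv, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        ai = a[valid] - 1
        bi = b[valid] - 1
        flat = np.bincount(ai * Ng + bi, minlength=Ng * Ng).reshape(Ng, Ng)
        counts += flat + flat.T  # both orderings -> symmetric
    total = counts.sum()
    if total == 0:
        raise DegenerateMatrixError("no in-mask voxel pair at this distance")
    return GLCMatrix(p=counts / total, distance=distance, Ng=Ng)


def build_glrlm(droi: DiscretizedRoi) -> RunLengthMatrix:
    """Maximal constant-level runs along each of the 13 directions.

    Runs break wherever the next voxel is outside the mask or carries a
    different level.  Counts are merged across directions, so
    sum_ij j * r(i,j) = Np * 13.
    """
    lv = _crop_levels(droi)
    Ng = droi.Ng
    Np = int((lv > 0).sum())
    shape = np.array(lv.shape)
    per_level: dict[tuple[int, int], int] = {}
    max_len = 1
    for d in DIRECTIONS_13:
        dv = np.array(d)
        # run starts: in-mask voxels whose predecessor along -d differs
        prev = np.zeros_like(lv)
        a, b = _offset_views(prev, d)
        src_a, src_b = _offset_views(lv, d)
        # voxel at position p has predecessor p - d; write lv[p-d] into prev[p]
        b[...] = src_a
        starts = np.argwhere((lv > 0) & (prev != lv))
        start_levels = lv[tuple(starts.T)]
        lengths = np.ones(len(starts), dtype=np.int64)
        pos = starts + dv
        active = np.arange(len(starts))
        while active.size:
            p = pos[active]
            inside = np.all((p >= 0) & (p < shape), axis=1)
            cont_mask = np.zeros(active.size, dtype=bool)
            if inside.any():
                pi = p[inside]
                cont_mask[inside] = lv[tuple(pi.T)] == start_levels[active[inside]]
            cont = active[cont_mask]
            lengths[cont] += 1
            pos[cont] += dv
            active = cont
        if len(lengths):
            max_len = max(max_len, int(lengths.max()))
        for lev, ln in zip(start_levels, lengths):
            per_level[(int(lev), int(ln))] = per_level.get((int(lev), int(ln)), 0) + 1
    counts = np.zeros((Ng, max_len), dtype=np.int64)
    for (lev, ln), c in per_level.items():
        counts[lev - 1, ln - 1] = c
    return RunLengthMatrix(counts=counts, Nr=int(counts.sum()), Np=Np)


def _label_zones(lv: np.ndarray, Ng: int):
    """Yield (level, zone_sizes, labeled, n_zones) per occupied gray level."""
    for level in range(1, Ng + 1):
        where = lv == level
        if not where.any():
            continue
        labeled, n = ndimage.label(where, structure=_STRUCT_26)
        sizes = np.bincount(labeled.ravel())[1:]  # drop background
        yield level, sizes, labeled, n


def build_glszm(droi: DiscretizedRoi) -> SizeZoneMatrix:
    """Size-zone counts: 26-connected equal-level components by size."""
    lv = _crop_levels(droi)
    Ng = droi.Ng
    Np = int((lv > 0).sum())
    rows: list[tuple[int, np.ndarray]] = [(level, sizes) for level, sizes, _, _ in _label_zones(lv, Ng)]
    smax = max(int(s.max()) for _, s in rows)
    counts = np.zeros((Ng, smax), dtype=np.int64)
    for level, sizes in rows:
        for s, c in zip(*np.unique(sizes, return_counts=True)):
            counts[level - 1, int(s) - 1] = int(c)
    return SizeZoneMatrix(counts=counts, Nz=int(counts.sum()), Np=Np)


def build_gldzm(droi: DiscretizedRoi) -> DistanceZoneMatrix:
    """Distance-zone counts: zones as in the GLSZM, tabulated by the
    minimum over the zone's voxels of the city-block distance to the ROI
    border (border voxels have distance 1)."""
    lv = _crop_levels(droi)
    Ng = droi.Ng
    Np = int((lv > 0).sum())
    mask = lv > 0
    padded = np.pad(mask, 1)  # image edge counts as border
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1, 1:-1]
    entries: dict[tuple[int, int], int] = {}
    dmax = 1
    for level, _, labeled, n in _label_zones(lv, Ng):
        zone_min = ndimage.minimum(dist, labels=labeled, index=np.arange(1, n + 1))
        for d in np.atleast_1d(zone_min):
            d = int(d)
            dmax = max(dmax, d)
            entries[(level, d)] = entries.get((level, d), 0) + 1
    counts = np.zeros((Ng, dmax), dtype=np.int64)
    for (level, d), c in entries.items():
        counts[level - 1, d - 1] = c
    return DistanceZoneMatrix(counts=counts, Nz=int(counts.sum()), Np=Np)


def build_ngtdm(droi: DiscretizedRoi) -> NeighborhoodDifferenceTable:
    """For each in-mask voxel with >= 1 in-mask 26-neighbor, accumulate
    |level - mean(neighbor levels)| into s_i of its level."""
    lv = _crop_levels(droi)
    Ng = droi.Ng
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    in_mask = lv > 0
    nbr_sum = ndimage.correlate(lv.astype(np.float64), kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(in_mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = in_mask & (nbr_cnt > 0.5)
    diffs = np.abs(lv[valid] - nbr_sum[valid] / nbr_cnt[valid])
    levels = lv[valid]
    s = np.zeros(Ng)
    n = np.zeros(Ng, dtype=np.int64)
    np.add.at(s, levels - 1, diffs)
    np.add.at(n, levels - 1, 1)
    return NeighborhoodDifferenceTable(s=s, n=n, Ng=Ng)
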