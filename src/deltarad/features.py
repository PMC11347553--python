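"""Radiomics feature computation.

Feature vectors map keys of the form ``image.family.name`` (image in
{original, gradient}; family in {shape, firstorder, glcm, glrlm, glszm,
gldzm, ngtdm}) to scalar values.  Where the image biomarker
standardisation initiative defines a permanent 4-character identifier for
a feature, it is attached to the serialized output.

Conventions that matter downstream:

* Kurtosis is the non-excess (Pearson) convention m4/m2^2 — a normal
  sample gives ~3, not ~0.
* All entropies are base 2 with 0*log(0) == 0 and no epsilon inside logs.
* Undefined values (zero variance, single gray level, degenerate
  matrices) are carried as NaN — explicitly undefined, never silently 0.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from typing import Iterator

import numpy as np
from skimage import measure

from .discretize import DiscretizationConfig, discretize, gradient_magnitude
from .errors import DegenerateMatrixError
from .imaging import ImageVolume, RoiExtract, RoiMask, apply_roi, check_geometry
from .matrices import (
    DistanceZoneMatrix,
    GLCMatrix,
    NeighborhoodDifferenceTable,
    RunLengthMatrix,
    SizeZoneMatrix,
    build_glcm,
    build_gldzm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
)

logger = logging.getLogger(__name__)

UNDEFINED = float("nan")

#: IBSI permanent identifiers, keyed by bare feature name.
IBSI_IDS: dict[str, str] = {
    "SurfaceVolumeRatio": "2PR5",
    "MinorAxisLength": "P9VJ",
    "Kurtosis": "IPH6",
    "ZonePercentage": "P30P",
    "ZoneEntropy": "GU8N",
    "SmallAreaLowGrayLevelEmphasis": "5RAI",
    "ShortRunEmphasis": "22OV",
    "InverseVariance": "E8JP",
    "InformationalMeasureOfCorrelation1": "R8DG",
    "InverseDifferenceNormalized": "NDRX",
    "RunEntropy": "HJ9O",
}

#: The feature set every extraction guarantees to report (the selected
#: delta-radiomics panel: shape, intensity and texture descriptors on the
#: original image plus gradient-image texture analogues).
MANDATORY_FEATURES: tuple[str, ...] = (
    "original.shape.SurfaceVolumeRatio",
    "original.shape.MinorAxisLength",
    "original.firstorder.Kurtosis",
    "original.glszm.ZonePercentage",
    "original.glszm.ZoneEntropy",
    "original.glszm.SmallAreaLowGrayLevelEmphasis",
    "original.glrlm.ShortRunEmphasis",
    "original.glcm.InverseVariance",
    "original.glcm.InformationalMeasureOfCorrelation1",
    "original.glcm.InverseDifferenceNormalized",
    "gradient.firstorder.Kurtosis",
    "gradient.glrlm.ShortRunEmphasis",
    "gradient.glrlm.RunEntropy",
    "gradient.glcm.InverseDifferenceNormalized",
)


class FeatureVector(Mapping):
    """Immutable named feature -> value map.

    Undefined features hold NaN; :meth:`defined` distinguishes them from
    finite values.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        self._values = dict(values)

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:
        return f"FeatureVector({len(self)} features)"

    def defined(self, key: str) -> bool:
        return math.isfinite(self._values[key])

    def prefixed(self, prefix: str) -> "FeatureVector":
        return FeatureVector({f"{prefix}.{k}": v for k, v in self._values.items()})

    @staticmethod
    def ibsi_id(key: str) -> str:
        return IBSI_IDS.get(key.rsplit(".", 1)[-1], "")

    def merge(self, *others: "FeatureVector") -> "FeatureVector":
        out = dict(self._values)
        for fv in others:
            dup = out.keys() & fv.keys()
            if dup:
                raise ValueError(f"duplicate feature keys: {sorted(dup)[:3]}")
            out.update(fv)
        return FeatureVector(out)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# first order


def first_order_features(roi: RoiExtract, bin_width: float = 50.0) -> FeatureVector:
    """Intensity statistics of the masked voxels.

    Entropy and uniformity use the same fixed-bin-width histogram
    (anchored at the ROI minimum) as the texture discretization.
    Kurtosis/skewness use population central moments; both are undefined
    (NaN) for a constant ROI.
    """
    v = roi.intensities
    if v.size < 2:
        raise ValueError("first-order features need >= 2 voxels")
    mean = float(v.mean())
    d = v - mean
    m2 = float((d**2).mean())
    m3 = float((d**3).mean())
    m4 = float((d**4).mean())
    skew = m3 / m2**1.5 if m2 > 0 else UNDEFINED
    kurt = m4 / m2**2 if m2 > 0 else UNDEFINED
    levels = np.floor((v - v.min()) / bin_width).astype(np.int64)
    p = np.bincount(levels) / v.size
    q10, q25, median, q75, q90 = np.percentile(v, [10, 25, 50, 75, 90])
    return FeatureVector(
        {
            "firstorder.Mean": mean,
            "firstorder.Median": float(median),
            "firstorder.Minimum": float(v.min()),
            "firstorder.Maximum": float(v.max()),
            "firstorder.Range": float(v.max() - v.min()),
            "firstorder.Percentile10": float(q10),
            "firstorder.Percentile90": float(q90),
            "firstorder.InterquartileRange": float(q75 - q25),
            "firstorder.Variance": m2,
            "firstorder.StandardDeviation": math.sqrt(m2),
            "firstorder.Skewness": skew,
            "firstorder.Kurtosis": kurt,
            "firstorder.Energy": float((v**2).sum()),
            "firstorder.RootMeanSquared": float(np.sqrt((v**2).mean())),
            "firstorder.MeanAbsoluteDeviation": float(np.abs(d).mean()),
            "firstorder.Entropy": _entropy(p),
            "firstorder.Uniformity": float((p**2).sum()),
        }
    )


# ---------------------------------------------------------------------------
# shape


#: Gaussian pre-smoothing (in voxels) applied to the binary mask before
#: marching cubes; counteracts the staircase overestimation of surface
#: area on voxelized shapes (a digitized ball's raw mesh area is ~9% high).
_MESH_SMOOTHING_VOX = 0.8


def _mesh_area_volume(mask: RoiMask) -> tuple[float, float]:
    from scipy import ndimage as _ndi

    padded = np.pad(mask.flags, 1).astype(np.float64)
    padded = _ndi.gaussian_filter(padded, _MESH_SMOOTHING_VOX)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    volume = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    return area, volume


def shape_features(mask: RoiMask, spacing: tuple[float, float, float] | None = None) -> FeatureVector:
    """Morphological descriptors of the mask.

    Surface area and volume come from a marching-cubes mesh of the
    (zero-padded, lightly anti-aliased) mask.  Axis lengths derive from
    the eigenvalues of the covariance of foreground voxel physical
    coordinates, calibrated to the equivalent uniform ellipsoid
    (axis length = 2*sqrt(5*eigenvalue)), so a ball of radius r reports
    a diameter of 2r.  This differs from the Gaussian-calibrated
    4*sqrt(eigenvalue) convention by a constant factor 1.118 which
    cancels in any relative (delta) change.  If the mesh is degenerate
    (e.g. a single voxel), voxel-face surface and voxel volume are used
    instead and a warning is logged.
    """
    sp = spacing or mask.spacing
    nvox = mask.voxel_count
    voxel_volume = float(np.prod(sp))
    try:
        area, volume = _mesh_area_volume(mask)
        if volume <= 0:
            raise ValueError("degenerate mesh volume")
    except Exception:  # pragma: no cover - rare degenerate meshes
        logger.warning("marching-cubes mesh degenerate; using voxel-count surface/volume")
        face_areas = (sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1])
        area = 0.0
        padded = np.pad(mask.flags, 1)
        for axis, fa in enumerate(face_areas):
            diff = np.diff(padded.astype(np.int8), axis=axis)
            area += float(np.abs(diff).sum()) * fa
        volume = nvox * voxel_volume
    coords = np.argwhere(mask.flags) * np.asarray(sp)
    if nvox >= 2:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
        major, minor, least = (2.0 * math.sqrt(5.0 * e) for e in eig)
        elongation = math.sqrt(eig[1] / eig[0]) if eig[0] > 0 else UNDEFINED
        flatness = math.sqrt(eig[2] / eig[0]) if eig[0] > 0 else UNDEFINED
    else:
        major = minor = least = elongation = flatness = UNDEFINED
    return FeatureVector(
        {
            "shape.MeshVolume": volume,
            "shape.VoxelVolume": nvox * voxel_volume,
            "shape.SurfaceArea": area,
            "shape.SurfaceVolumeRatio": area / volume,
            "shape.Sphericity": (36.0 * math.pi * volume**2) ** (1.0 / 3.0) / area,
            "shape.MajorAxisLength": major,
            "shape.MinorAxisLength": minor,
            "shape.LeastAxisLength": least,
            "shape.Elongation": elongation,
            "shape.Flatness": flatness,
        }
    )


# ---------------------------------------------------------------------------
# GLCM


def glcm_features(m: GLCMatrix) -> FeatureVector:
    """Co-occurrence features of a normalized symmetric GLCM."""
    p = m.p
    Ng = m.Ng
    i = np.arange(1, Ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((ii * p).sum())
    sigma2 = float(((ii - mu) ** 2 * p).sum())
    absdiff = np.abs(ii - jj)
    # difference / sum distributions
    pdiff = np.zeros(Ng)
    np.add.at(pdiff, absdiff.ravel(), p.ravel())
    psum = np.zeros(2 * Ng - 1)
    np.add.at(psum, (ii + jj - 2).ravel(), p.ravel())
    k_diff = np.arange(Ng)
    k_sum = np.arange(2, 2 * Ng + 1)
    diff_avg = float((k_diff * pdiff).sum())
    off = ii != jj
    inv_var = float((p[off] / (ii - jj)[off].astype(float) ** 2).sum()) if off.any() else 0.0
    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    pospair = p > 0
    outer = np.outer(px, px)
    hxy1 = float(-(p[pospair] * np.log2(outer[pospair])).sum()) if pospair.any() else 0.0
    outer_pos = outer > 0
    hxy2 = float(-(outer[outer_pos] * np.log2(outer[outer_pos])).sum())
    if hx > 0:
        imc1 = (hxy - hxy1) / hx
        imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    else:
        imc1 = UNDEFINED
        imc2 = UNDEFINED
    corr = float(((ii - mu) * (jj - mu) * p).sum() / sigma2) if sigma2 > 0 else UNDEFINED
    return FeatureVector(
        {
            "glcm.JointMaximum": float(p.max()),
            "glcm.JointAverage": mu,
            "glcm.JointVariance": sigma2,
            "glcm.JointEntropy": hxy,
            "glcm.AngularSecondMoment": float((p**2).sum()),
            "glcm.Contrast": float(((ii - jj) ** 2 * p).sum()),
            "glcm.Dissimilarity": diff_avg,
            "glcm.DifferenceAverage": diff_avg,
            "glcm.DifferenceVariance": float(((k_diff - diff_avg) ** 2 * pdiff).sum()),
            "glcm.DifferenceEntropy": _entropy(pdiff),
            "glcm.SumAverage": float((k_sum * psum).sum()),
            "glcm.SumEntropy": _entropy(psum),
            "glcm.InverseDifference": float((p / (1.0 + absdiff)).sum()),
            "glcm.InverseDifferenceNormalized": float((p / (1.0 + absdiff / Ng)).sum()),
            "glcm.InverseDifferenceMoment": float((p / (1.0 + absdiff**2)).sum()),
            "glcm.InverseDifferenceMomentNormalized": float((p / (1.0 + (absdiff / Ng) ** 2)).sum()),
            "glcm.InverseVariance": inv_var,
            "glcm.Correlation": corr,
            "glcm.Autocorrelation": float((ii * jj * p).sum()),
            "glcm.ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
            "glcm.ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
            "glcm.ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
            "glcm.InformationalMeasureOfCorrelation1": imc1,
            "glcm.InformationalMeasureOfCorrelation2": imc2,
        }
    )


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_features(m: RunLengthMatrix) -> FeatureVector:
    r = m.counts.astype(np.float64)
    Nr = float(m.Nr)
    i = np.arange(1, r.shape[0] + 1)[:, None]
    j = np.arange(1, r.shape[1] + 1)[None, :]
    ri = r.sum(axis=1)
    rj = r.sum(axis=0)
    q = r / Nr
    mu_i = float((i * q).sum())
    mu_j = float((j * q).sum())
    return FeatureVector(
        {
            "glrlm.ShortRunEmphasis": float((r / j**2).sum() / Nr),
            "glrlm.LongRunEmphasis": float((r * j**2).sum() / Nr),
            "glrlm.LowGrayLevelRunEmphasis": float((r / i**2).sum() / Nr),
            "glrlm.HighGrayLevelRunEmphasis": float((r * i**2).sum() / Nr),
            "glrlm.ShortRunLowGrayLevelEmphasis": float((r / (i**2 * j**2)).sum() / Nr),
            "glrlm.ShortRunHighGrayLevelEmphasis": float((r * i**2 / j**2).sum() / Nr),
            "glrlm.LongRunLowGrayLevelEmphasis": float((r * j**2 / i**2).sum() / Nr),
            "glrlm.LongRunHighGrayLevelEmphasis": float((r * i**2 * j**2).sum() / Nr),
            "glrlm.GrayLevelNonUniformity": float((ri**2).sum() / Nr),
            "glrlm.GrayLevelNonUniformityNormalized": float((ri**2).sum() / Nr**2),
            "glrlm.RunLengthNonUniformity": float((rj**2).sum() / Nr),
            "glrlm.RunLengthNonUniformityNormalized": float((rj**2).sum() / Nr**2),
            "glrlm.RunPercentage": Nr / (m.Np * m.n_directions),
            "glrlm.GrayLevelVariance": float(((i - mu_i) ** 2 * q).sum()),
            "glrlm.RunLengthVariance": float(((j - mu_j) ** 2 * q).sum()),
            "glrlm.RunEntropy": _entropy(q.ravel()),
        }
    )


# ---------------------------------------------------------------------------
# GLSZM


def glszm_features(m: SizeZoneMatrix) -> FeatureVector:
    z = m.counts.astype(np.float64)
    Nz = float(m.Nz)
    i = np.arange(1, z.shape[0] + 1)[:, None]
    s = np.arange(1, z.shape[1] + 1)[None, :]
    zi = z.sum(axis=1)
    zs = z.sum(axis=0)
    q = z / Nz
    mu_i = float((i * q).sum())
    mu_s = float((s * q).sum())
    return FeatureVector(
        {
            "glszm.SmallAreaEmphasis": float((z / s**2).sum() / Nz),
            "glszm.LargeAreaEmphasis": float((z * s**2).sum() / Nz),
            "glszm.LowGrayLevelZoneEmphasis": float((z / i**2).sum() / Nz),
            "glszm.HighGrayLevelZoneEmphasis": float((z * i**2).sum() / Nz),
            "glszm.SmallAreaLowGrayLevelEmphasis": float((z / (i**2 * s**2)).sum() / Nz),
            "glszm.SmallAreaHighGrayLevelEmphasis": float((z * i**2 / s**2).sum() / Nz),
            "glszm.LargeAreaLowGrayLevelEmphasis": float((z * s**2 / i**2).sum() / Nz),
            "glszm.LargeAreaHighGrayLevelEmphasis": float((z * i**2 * s**2).sum() / Nz),
            "glszm.GrayLevelNonUniformity": float((zi**2).sum() / Nz),
            "glszm.GrayLevelNonUniformityNormalized": float((zi**2).sum() / Nz**2),
            "glszm.SizeZoneNonUniformity": float((zs**2).sum() / Nz),
            "glszm.SizeZoneNonUniformityNormalized": float((zs**2).sum() / Nz**2),
            "glszm.ZonePercentage": Nz / m.Np,
            "glszm.GrayLevelVariance": float(((i - mu_i) ** 2 * q).sum()),
            "glszm.ZoneSizeVariance": float(((s - mu_s) ** 2 * q).sum()),
            "glszm.ZoneEntropy": _entropy(q.ravel()),
        }
    )


# ---------------------------------------------------------------------------
# GLDZM


def gldzm_features(m: DistanceZoneMatrix) -> FeatureVector:
    z = m.counts.astype(np.float64)
    Nz = float(m.Nz)
    i = np.arange(1, z.shape[0] + 1)[:, None]
    d = np.arange(1, z.shape[1] + 1)[None, :]
    zd = z.sum(axis=0)
    q = z / Nz
    mu_i = float((i * q).sum())
    mu_d = float((d * q).sum())
    return FeatureVector(
        {
            "gldzm.SmallDistanceEmphasis": float((z / d**2).sum() / Nz),
            "gldzm.LargeDistanceEmphasis": float((z * d**2).sum() / Nz),
            "gldzm.LowGrayLevelZoneEmphasis": float((z / i**2).sum() / Nz),
            "gldzm.HighGrayLevelZoneEmphasis": float((z * i**2).sum() / Nz),
            "gldzm.SmallDistanceLowGrayLevelEmphasis": float((z / (i**2 * d**2)).sum() / Nz),
            "gldzm.SmallDistanceHighGrayLevelEmphasis": float((z * i**2 / d**2).sum() / Nz),
            "gldzm.LargeDistanceLowGrayLevelEmphasis": float((z * d**2 / i**2).sum() / Nz),
            "gldzm.LargeDistanceHighGrayLevelEmphasis": float((z * i**2 * d**2).sum() / Nz),
            "gldzm.ZoneDistanceNonUniformity": float((zd**2).sum() / Nz),
            "gldzm.ZoneDistanceNonUniformityNormalized": float((zd**2).sum() / Nz**2),
            "gldzm.GrayLevelVariance": float(((i - mu_i) ** 2 * q).sum()),
            "gldzm.ZoneDistanceVariance": float(((d - mu_d) ** 2 * q).sum()),
            "gldzm.ZoneDistanceEntropy": _entropy(q.ravel()),
        }
    )


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(t: NeighborhoodDifferenceTable) -> FeatureVector:
    Nv = t.Nv
    if Nv == 0:
        return FeatureVector({f"ngtdm.{k}": UNDEFINED for k in
                              ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")})
    pi = t.n / Nv
    s = t.s
    i = np.arange(1, t.Ng + 1, dtype=np.float64)
    present = pi > 0
    npres = int(present.sum())
    ps_sum = float((pi * s).sum())
    coarseness = 1.0 / ps_sum if ps_sum > 0 else 1e6
    if npres > 1:
        pij = np.outer(pi[present], pi[present])
        dij = (i[present][:, None] - i[present][None, :])
        contrast = float((pij * dij**2).sum()) / (npres * (npres - 1)) * float(s.sum()) / Nv
        denom = float(np.abs(i[present][:, None] * pi[present][:, None]
                             - i[present][None, :] * pi[present][None, :]).sum())
        busyness = ps_sum / denom if denom > 0 else UNDEFINED
        num = np.abs(dij) * (pi[present][:, None] * s[present][:, None]
                             + pi[present][None, :] * s[present][None, :])
        pij_sum = pi[present][:, None] + pi[present][None, :]
        complexity = float((num / pij_sum).sum()) / Nv
        strength_num = float((pij_sum * dij**2).sum())
        strength = strength_num / float(s.sum()) if s.sum() > 0 else UNDEFINED
    else:
        contrast = 0.0
        busyness = UNDEFINED
        complexity = 0.0
        strength = UNDEFINED if s.sum() == 0 else 0.0
    return FeatureVector(
        {
            "ngtdm.Coarseness": coarseness,
            "ngtdm.Contrast": contrast,
            "ngtdm.Busyness": busyness,
            "ngtdm.Complexity": complexity,
            "ngtdm.Strength": strength,
        }
    )


# ---------------------------------------------------------------------------
# full extraction


def _texture_families(volume: ImageVolume, mask: RoiMask, cfg: DiscretizationConfig,
                      glcm_distance: int) -> FeatureVector:
    droi = discretize(volume, mask, cfg)
    try:
        fv_glcm = glcm_features(build_glcm(droi, distance=glcm_distance))
    except DegenerateMatrixError:
        fv_glcm = FeatureVector({k: UNDEFINED for k in glcm_features.__wrapped_keys__})
    fv = fv_glcm.merge(
        glrlm_features(build_glrlm(droi)),
        glszm_features(build_glszm(droi)),
        gldzm_features(build_gldzm(droi)),
        ngtdm_features(build_ngtdm(droi)),
    )
    return fv


def extract_all(
    volume: ImageVolume,
    mask: RoiMask,
    cfg: DiscretizationConfig | None = None,
    glcm_distance: int = 1,
) -> FeatureVector:
    """Full feature vector over the original and gradient-magnitude images.

    Shape features are computed once from the mask alone.  First-order and
    the five texture families are computed on the original volume and on
    its gradient-magnitude image, each discretized with the same
    fixed-bin-width rule.  Individual undefined features are reported as
    NaN and never abort the extraction; geometry errors propagate.
    """
    cfg = cfg or DiscretizationConfig()
    check_geometry(volume, mask)
    parts = [shape_features(mask).prefixed("original")]
    grad = gradient_magnitude(volume)
    for image_name, img in (("original", volume), ("gradient", grad)):
        roi = apply_roi(img, mask)
        if roi.voxel_count >= 2:
            fo = first_order_features(roi, bin_width=cfg.bin_width)
        else:  # single-voxel ROI: statistics undefined, extraction continues
            fo = FeatureVector({k: UNDEFINED for k in _FIRSTORDER_KEYS})
        parts.append(fo.prefixed(image_name))
        parts.append(_texture_families(img, mask, cfg, glcm_distance).prefixed(image_name))
    fv = parts[0].merge(*parts[1:])
    missing = [k for k in MANDATORY_FEATURES if k not in fv]
    if missing:  # defensive: the roster above always includes them
        raise RuntimeError(f"mandatory features missing from extraction: {missing}")
    return fv


# ---------------------------------------------------------------------------
# serialization


def features_to_long_frame(features: "dict[str, dict[str, FeatureVector]]"):
    """Flatten nested patient -> timepoint -> FeatureVector maps to the
    long CSV schema (patient_id, timepoint, image, family, feature,
    ibsi_id, value, defined_flag)."""
    import pandas as pd

    rows = []
    for pid, by_tp in features.items():
        for tp, fv in by_tp.items():
            for key, val in fv.items():
                image, family, name = key.split(".", 2)
                rows.append(
                    {
                        "patient_id": pid,
                        "timepoint": tp,
                        "image": image,
                        "family": family,
                        "feature": name,
                        "ibsi_id": IBSI_IDS.get(name, ""),
                        "value": val,
                        "defined_flag": math.isfinite(val),
                    }
                )
    return pd.DataFrame(rows)


def long_frame_to_features(df) -> "dict[str, dict[str, FeatureVector]]":
    """Inverse of :func:`features_to_long_frame`."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for row in df.itertuples(index=False):
        key = f"{row.image}.{row.family}.{row.feature}"
        out.setdefault(row.patient_id, {}).setdefault(row.timepoint, {})[key] = float(row.value)
    return {pid: {tp: FeatureVector(vals) for tp, vals in by_tp.items()} for pid, by_tp in out.items()}


# keys emitted by glcm_features, for the degenerate-matrix fallback
glcm_features.__wrapped_keys__ = tuple(
    glcm_features(GLCMatrix(p=np.array([[1.0]]), distance=1, Ng=1)).keys()
)

# keys emitted by first_order_features, for the single-voxel fallback
_FIRSTORDER_KEYS = tuple(first_order_features(
    RoiExtract(np.array([0.0, 1.0]), 2, ((0, 0), (0, 0), (0, 1)))
).keys())
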