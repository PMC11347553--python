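"""Synthetic longitudinal ADC cohorts.

Generates complete cohorts — tumor phantoms at baseline and follow-up,
RECIST labels, treatment arms and censored survival times — carrying the
statistical structure the analysis pipeline assumes, so every stage can
be exercised without patient data.

The phantom is an ellipsoidal low-ADC lesion (ADC in 10^-6 mm^2/s) with
spatially correlated Gaussian texture inside a higher-ADC background.
Treatment response is implanted in *image space*, not feature space:

* responders get randomly placed patches of elevated ADC (locally
  increased diffusivity after cell death) that fragment the texture —
  short-run emphasis and zone percentage rise, inverse difference
  normalized falls;
* non-responders get in-mask smoothing (uniformly restricted diffusion
  over a homogeneous, dense tumor) and optional axis growth — the same
  features move the opposite way.

Follow-up effects ramp in with a saturating time factor
1 - exp(-day / tau), so a day-1 scan carries roughly half the asymptotic
effect and a day-14 scan nearly all of it.

Survival is exponential with a class-dependent median (long-PFS group
363 d, short-PFS group 180 d — the latter holding every progressive-
disease patient plus the weak-responder fraction of stable disease),
with independent uniform right censoring.

All randomness derives from a master seed through a documented counter
scheme: numpy SeedSequence([master_seed, patient_index, stage]), with
stage 0 = baseline phantom, 10+k = k-th follow-up, 100 = survival,
200 = cohort-level assignments.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .discretize import DiscretizationConfig
from .errors import ConfigError
from .features import FeatureVector, extract_all
from .imaging import ImageVolume, RoiMask, write_mask, write_volume

LN2 = math.log(2.0)

# stage codes of the per-patient seed counter scheme
_STAGE_BASELINE = 0
_STAGE_FOLLOWUP = 10  # + follow-up index
_STAGE_SURVIVAL = 100
_STAGE_COHORT = 200


def _rng(master_seed: int, patient_index: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(patient_index), int(stage)]))


# ---------------------------------------------------------------------------
# phantom


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity statistics of a single tumor phantom.

    Grid defaults follow a typical 2D-EPI diffusion acquisition matrix
    (104 x 136, 25 slices at 6 mm spacing); ADC values are in
    10^-6 mm^2/s so a discretization bin width of 50 is meaningful.
    """

    shape: tuple[int, int, int] = (104, 136, 25)
    spacing: tuple[float, float, float] = (3.3, 3.3, 6.0)
    tumor_radius_mm: float = 20.0
    tumor_adc_mean: float = 900.0
    tumor_adc_sd: float = 150.0
    background_adc: float = 1500.0
    texture_correlation_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.tumor_adc_sd < 0:
            raise ConfigError("tumor_adc_sd must be >= 0")
        half_extent = [0.5 * n * s for n, s in zip(self.shape, self.spacing)]
        if any(self.tumor_radius_mm >= h for h in half_extent):
            raise ConfigError(
                f"tumor radius {self.tumor_radius_mm} mm does not fit the grid "
                f"(half-extents {half_extent} mm)"
            )


def _correlated_noise(shape, spacing, correlation_mm, rng) -> np.ndarray:
    white = rng.standard_normal(shape)
    sigma = [max(correlation_mm / s, 1e-6) for s in spacing]
    return ndimage.gaussian_filter(white, sigma=sigma)


def make_phantom(cfg: PhantomConfig, seed: int | np.random.Generator = 0) -> tuple[ImageVolume, RoiMask]:
    """Ellipsoidal low-ADC tumor with correlated texture in a uniform
    higher-ADC background.  The in-mask sample mean and SD are rescaled to
    the configured values exactly; reproducible from the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = (np.asarray(cfg.shape) - 1) / 2.0
    grids = np.meshgrid(*(np.arange(n) for n in cfg.shape), indexing="ij")
    r2 = sum(((g - c) * s / cfg.tumor_radius_mm) ** 2 for g, c, s in zip(grids, center, cfg.spacing))
    flags = r2 <= 1.0
    vox = np.full(cfg.shape, cfg.background_adc, dtype=np.float64)
    if cfg.tumor_adc_sd > 0:
        noise = _correlated_noise(cfg.shape, cfg.spacing, cfg.texture_correlation_mm, rng)
        sample = noise[flags]
        noise = (noise - sample.mean()) / sample.std()
        vox[flags] = cfg.tumor_adc_mean + cfg.tumor_adc_sd * noise[flags]
    else:
        vox[flags] = cfg.tumor_adc_mean
    return ImageVolume(vox, cfg.spacing), RoiMask(flags, cfg.spacing)


# ---------------------------------------------------------------------------
# response evolution


@dataclass(frozen=True)
class ResponseModel:
    """How a tumor's image changes from baseline to follow-up.

    sparsification_fraction — fraction of tumor voxels covered by
    elevated-ADC patches (responder mechanism); patch ADC moves
    `patch_elevation` of the way toward `elevated_adc`.
    homogenization_strength — blend weight toward an in-mask smoothed
    image (non-responder mechanism; `smoothing_mm` is the Gaussian
    width).  growth_factor scales the lesion isotropically about its
    centroid (>1 growth, <1 shrinkage).  rescan_noise_sd adds correlated
    acquisition noise to the follow-up so repeat scans are never
    bit-identical.
    """

    label: str = "responder_SD"
    sparsification_fraction: float = 0.0
    patch_radius_mm: float = 5.0
    patch_elevation: float = 0.4
    elevated_adc: float = 1500.0
    homogenization_strength: float = 0.0
    smoothing_mm: float = 8.0
    growth_factor: float = 1.0
    rescan_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sparsification_fraction <= 1.0:
            raise ConfigError("sparsification_fraction must be in [0, 1]")
        if not 0.0 <= self.homogenization_strength <= 1.0:
            raise ConfigError("homogenization_strength must be in [0, 1]")
        if self.growth_factor <= 0:
            raise ConfigError("growth_factor must be positive")


#: Default response profiles.  PR responds strongly, responding SD mildly;
#: non-responding SD homogenizes mildly, PD homogenizes strongly and
#: grows ~10% along every axis.  Magnitudes are calibration constants
#: chosen so pooled mean deltas land on the scale reported for such
#: cohorts (zone-percentage change around +0.2 in responders / -0.1 in
#: non-responders); see docs/methods.md.
DEFAULT_RESPONSE_MODELS: dict[str, ResponseModel] = {
    "responder_PR": ResponseModel(label="responder_PR", sparsification_fraction=0.35),
    "responder_SD": ResponseModel(label="responder_SD", sparsification_fraction=0.20),
    "nonresponder_SD": ResponseModel(
        label="nonresponder_SD", homogenization_strength=0.6, growth_factor=1.03
    ),
    "nonresponder_PD": ResponseModel(
        label="nonresponder_PD", homogenization_strength=1.0, growth_factor=1.10
    ),
}


def _scale_about_centroid(arr: np.ndarray, centroid: np.ndarray, factor: float, order: int) -> np.ndarray:
    matrix = np.diag([1.0 / factor] * 3)
    offset = centroid * (1.0 - 1.0 / factor)
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order, mode="nearest")


def evolve_phantom(
    baseline: ImageVolume,
    mask: RoiMask,
    model: ResponseModel,
    seed: int | np.random.Generator = 0,
    effect_scale: float = 1.0,
) -> tuple[ImageVolume, RoiMask]:
    """Apply a response model to a baseline phantom.

    `effect_scale` in [0, 1] attenuates every mechanism (used for early
    follow-ups).  With effect_scale 0 — or an all-zero model without
    rescan noise — the follow-up equals the baseline and every delta
    feature is exactly zero.
    """
    s = float(np.clip(effect_scale, 0.0, 1.0))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vox = baseline.voxels.copy()
    flags = mask.flags
    spacing = np.asarray(baseline.spacing)

    g_eff = 1.0 + (model.growth_factor - 1.0) * s
    if not np.isclose(g_eff, 1.0):
        centroid = np.argwhere(flags).mean(axis=0)
        flags = _scale_about_centroid(flags.astype(np.float64), centroid, g_eff, order=1) > 0.5
        scaled_vox = _scale_about_centroid(vox, centroid, g_eff, order=1)
        grown = flags & ~mask.flags
        vox[grown] = scaled_vox[grown]

    beta = model.homogenization_strength * s
    if beta > 0:
        # in-mask (normalized-convolution) smoothing: the tumor-background
        # boundary must not bleed into the homogenized lesion
        sigma = [model.smoothing_mm / sp for sp in spacing]
        num = ndimage.gaussian_filter(np.where(flags, vox, 0.0), sigma=sigma)
        den = ndimage.gaussian_filter(flags.astype(np.float64), sigma=sigma)
        smoothed = num[flags] / np.maximum(den[flags], 1e-9)
        vox[flags] = (1.0 - beta) * vox[flags] + beta * smoothed

    frac = model.sparsification_fraction * s
    if frac > 0:
        in_mask = np.argwhere(flags)
        n_target = int(round(frac * len(in_mask)))
        covered = np.zeros(len(in_mask), dtype=bool)
        # sphere offsets of the patch in index space
        rad_vox = np.maximum(np.floor(model.patch_radius_mm / spacing).astype(int), 0)
        offs = np.array(
            [
                (dx, dy, dz)
                for dx in range(-rad_vox[0], rad_vox[0] + 1)
                for dy in range(-rad_vox[1], rad_vox[1] + 1)
                for dz in range(-rad_vox[2], rad_vox[2] + 1)
                if sum((np.array([dx, dy, dz]) * spacing) ** 2) <= model.patch_radius_mm**2
            ]
        )
        pos_index = {tuple(p): i for i, p in enumerate(in_mask)}
        tries = 0
        while covered.sum() < n_target and tries < 50 * max(n_target, 1):
            tries += 1
            center = in_mask[rng.integers(len(in_mask))]
            patch = center + offs
            hit = [pos_index[t] for t in map(tuple, patch) if t in pos_index]
            newly = [i for i in hit if not covered[i]]
            if not newly:
                continue
            covered[newly] = True
            pts = tuple(in_mask[newly].T)
            vox[pts] = vox[pts] + model.patch_elevation * (model.elevated_adc - vox[pts])

    if model.rescan_noise_sd > 0:
        noise = _correlated_noise(baseline.shape, baseline.spacing, 4.0, rng)
        sample = noise[flags]
        noise = (noise - sample.mean()) / max(sample.std(), 1e-12)
        vox[flags] = vox[flags] + model.rescan_noise_sd * noise[flags]

    return ImageVolume(vox, baseline.spacing, baseline.origin), RoiMask(flags, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for a synthetic cohort.

    Cohort composition mirrors a 130-patient two-arm study: arms of
    64 (TKI; follow-up scans day 7 and 14) and 66 (PBC; day 1, with a
    17-patient subset re-scanned at day 7), response classes 40 PR /
    80 SD / 10 PD distributed over arms as 32/27/5 (TKI) and 8/53/5
    (PBC).  PFS is exponential with median 363 d in the long-PFS group
    and 180 d in the short-PFS group; the short group holds every PD
    patient plus the non-responding fraction of SD (default 0.525 of SD,
    i.e. ~42 patients, so the short group is ~40% of the cohort).
    """

    n_pr_tki: int = 32
    n_sd_tki: int = 27
    n_pd_tki: int = 5
    n_pr_pbc: int = 8
    n_sd_pbc: int = 53
    n_pd_pbc: int = 5
    n_pbc_fu2: int = 17
    sd_nonresponder_fraction: float = 0.525
    pfs_median_long: float = 363.0
    pfs_median_short: float = 180.0
    os_tail_median: float = 100.0
    pfs_censoring_fraction: float = 0.15
    os_censoring_fraction: float = 0.30
    tki_followup_days: tuple[int, ...] = (7, 14)
    pbc_followup_days: tuple[int, ...] = (1,)
    pbc_fu2_day: int = 7
    effect_time_constant_days: float = 1.5
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    response_models: dict[str, ResponseModel] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_MODELS)
    )
    null_effect: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name.startswith("n_") and getattr(self, f.name) < 0:
                raise ConfigError(f"{f.name} must be >= 0")
        if self.pfs_median_long <= 0 or self.pfs_median_short <= 0:
            raise ConfigError("PFS medians must be positive")

    @property
    def n_patients(self) -> int:
        return (self.n_pr_tki + self.n_sd_tki + self.n_pd_tki
                + self.n_pr_pbc + self.n_sd_pbc + self.n_pd_pbc)

    def effect_scale(self, day: int) -> float:
        return 1.0 - math.exp(-day / self.effect_time_constant_days)


@dataclass(frozen=True)
class PatientSpec:
    """Resolved per-patient simulation plan."""

    patient_id: str
    index: int
    arm: str
    recist: str
    long_pfs: bool
    profile: str
    followup_days: tuple[int, ...]

    @property
    def timepoints(self) -> tuple[str, ...]:
        return ("BL",) + tuple(f"FU{i + 1}" for i in range(len(self.followup_days)))


def plan_cohort(cfg: CohortConfig) -> list[PatientSpec]:
    """Assign arms, RECIST classes, latent outcome groups and response
    profiles to the whole cohort, deterministically from the master seed."""
    rng = _rng(cfg.master_seed, 0, _STAGE_COHORT)
    roster = (
        [("TKI", "PR")] * cfg.n_pr_tki + [("TKI", "SD")] * cfg.n_sd_tki + [("TKI", "PD")] * cfg.n_pd_tki
        + [("PBC", "PR")] * cfg.n_pr_pbc + [("PBC", "SD")] * cfg.n_sd_pbc + [("PBC", "PD")] * cfg.n_pd_pbc
    )
    sd_idx = [i for i, (_, rc) in enumerate(roster) if rc == "SD"]
    n_nonresp = int(round(cfg.sd_nonresponder_fraction * len(sd_idx)))
    sd_nonresp = set(rng.choice(sd_idx, size=n_nonresp, replace=False)) if n_nonresp else set()
    pbc_idx = [i for i, (arm, _) in enumerate(roster) if arm == "PBC"]
    pbc_fu2 = set(rng.choice(pbc_idx, size=min(cfg.n_pbc_fu2, len(pbc_idx)), replace=False))
    specs = []
    width = max(3, len(str(len(roster))))
    for i, (arm, recist) in enumerate(roster):
        if recist == "PR":
            profile, long_pfs = "responder_PR", True
        elif recist == "PD":
            profile, long_pfs = "nonresponder_PD", False
        elif i in sd_nonresp:
            profile, long_pfs = "nonresponder_SD", False
        else:
            profile, long_pfs = "responder_SD", True
        if cfg.null_effect:
            profile, long_pfs = "responder_SD", True
        days = cfg.tki_followup_days if arm == "TKI" else cfg.pbc_followup_days
        if arm == "PBC" and i in pbc_fu2:
            days = tuple(days) + (cfg.pbc_fu2_day,)
        specs.append(
            PatientSpec(
                patient_id=f"P{i + 1:0{width}d}",
                index=i,
                arm=arm,
                recist=recist,
                long_pfs=long_pfs,
                profile=profile,
                followup_days=tuple(days),
            )
        )
    return specs


def _censor_bound_factor(fraction: float) -> float:
    """Solve (1 - e^-x)/x = fraction: for T ~ Exp(rate lam) and an
    independent C ~ Uniform(0, x/lam), the censored fraction P(C < T)
    equals `fraction`."""
    from scipy.optimize import brentq

    return float(brentq(lambda x: (1.0 - math.exp(-x)) / x - fraction, 1e-9, 1e6))


def _censor(true_time: float, median: float, fraction: float, rng: np.random.Generator) -> tuple[float, int]:
    """Independent uniform right censoring at the configured expected
    fraction (non-informative, so Kaplan-Meier stays consistent)."""
    if fraction <= 0:
        return true_time, 1
    if fraction >= 1:
        return 0.0, 0
    upper = _censor_bound_factor(fraction) * median / LN2
    c = rng.uniform(0.0, upper)
    return (true_time, 1) if true_time <= c else (c, 0)


def simulate_survival(long_pfs: bool, cfg: CohortConfig, rng: np.random.Generator) -> tuple[float, int, float, int]:
    """Draw (pfs_days, pfs_event, os_days, os_event) for one patient.

    PFS ~ Exp with the group median; OS = PFS + an exponential tail.
    Right censoring is independent uniform, calibrated so the expected
    censored fraction matches the configuration.
    """
    median = cfg.pfs_median_long if long_pfs else cfg.pfs_median_short
    pfs_true = rng.exponential(median / LN2)
    os_true = pfs_true + rng.exponential(cfg.os_tail_median / LN2)
    pfs_days, pfs_event = _censor(pfs_true, median, cfg.pfs_censoring_fraction, rng)
    os_days, os_event = _censor(os_true, median + cfg.os_tail_median, cfg.os_censoring_fraction, rng)
    return float(pfs_days), pfs_event, float(os_days), os_event


def simulate_patient_images(
    spec: PatientSpec, cfg: CohortConfig
) -> dict[str, tuple[ImageVolume, RoiMask]]:
    """Baseline + follow-up volumes/masks for one patient."""
    rng_bl = _rng(cfg.master_seed, spec.index, _STAGE_BASELINE)
    baseline, mask = make_phantom(cfg.phantom, rng_bl)
    out = {"BL": (baseline, mask)}
    model = cfg.response_models[spec.profile]
    for k, day in enumerate(spec.followup_days):
        rng_fu = _rng(cfg.master_seed, spec.index, _STAGE_FOLLOWUP + k)
        out[f"FU{k + 1}"] = evolve_phantom(baseline, mask, model, rng_fu, effect_scale=cfg.effect_scale(day))
    return out


def simulate_clinical_table(cfg: CohortConfig, specs: list[PatientSpec] | None = None) -> pd.DataFrame:
    """Per-patient clinical table (arm, RECIST, censored PFS/OS)."""
    specs = specs or plan_cohort(cfg)
    rows = []
    for spec in specs:
        rng = _rng(cfg.master_seed, spec.index, _STAGE_SURVIVAL)
        pfs, pfs_e, osd, os_e = simulate_survival(spec.long_pfs, cfg, rng)
        rows.append(
            {
                "patient_id": spec.patient_id,
                "arm": spec.arm,
                "recist": spec.recist,
                "pfs_days": round(pfs, 1),
                "pfs_event": pfs_e,
                "os_days": round(osd, 1),
                "os_event": os_e,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort_features(
    cfg: CohortConfig,
    discretization: DiscretizationConfig | None = None,
) -> tuple[dict[str, dict[str, FeatureVector]], pd.DataFrame]:
    """Simulate the cohort and extract features, one patient at a time.

    Returns (features, clinical): features[patient_id][timepoint] is a
    FeatureVector for "BL", "FU1", ...; clinical is the CohortTable
    DataFrame.  Volumes are discarded after extraction, keeping memory
    flat in cohort size.
    """
    specs = plan_cohort(cfg)
    features: dict[str, dict[str, FeatureVector]] = {}
    for spec in specs:
        images = simulate_patient_images(spec, cfg)
        features[spec.patient_id] = {
            tp: extract_all(vol, msk, discretization) for tp, (vol, msk) in images.items()
        }
    return features, simulate_clinical_table(cfg, specs)


def simulate_cohort(cfg: CohortConfig, outdir: str | os.PathLike) -> pd.DataFrame:
    """Write a cohort directory tree consumable by the CLI end-to-end.

    Layout: <outdir>/<patient>_<timepoint>_adc.nii.gz and ..._mask.nii.gz
    per scan, clinical.csv with the cohort table, and config.json echoing
    the generating configuration.  Returns the clinical table.
    """
    os.makedirs(outdir, exist_ok=True)
    specs = plan_cohort(cfg)
    for spec in specs:
        for tp, (vol, msk) in simulate_patient_images(spec, cfg).items():
            write_volume(vol, os.path.join(outdir, f"{spec.patient_id}_{tp}_adc.nii.gz"))
            write_mask(msk, os.path.join(outdir, f"{spec.patient_id}_{tp}_mask.nii.gz"))
    clinical = simulate_clinical_table(cfg, specs)
    clinical.to_csv(os.path.join(outdir, "clinical.csv"), index=False)
    echo = dataclasses.asdict(cfg)
    echo["phantom"] = dataclasses.asdict(cfg.phantom)
    echo["response_models"] = {k: dataclasses.asdict(v) for k, v in cfg.response_models.items()}
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(echo, fh, indent=2, default=str)
    return clinical


def reduced_cohort_config(master_seed: int = 0, **overrides) -> CohortConfig:
    """Default cohort on a reduced 64 x 64 x 16 grid (full arm sizes,
    smaller phantoms) — the configuration used for desk-scale end-to-end
    validation."""
    phantom = PhantomConfig(shape=(64, 64, 16), spacing=(3.3, 3.3, 6.0), tumor_radius_mm=18.0)
    return CohortConfig(master_seed=master_seed, phantom=phantom, **overrides)
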