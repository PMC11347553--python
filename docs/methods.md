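# Methods

`deltarad` analyses longitudinal apparent-diffusion-coefficient (ADC) maps
of solid tumors: it quantifies each tumor ROI with radiomics features,
tracks their relative change between a baseline scan and follow-ups early
in a treatment course, and asks whether those changes stratify patients by
treatment response and survival. This note records the model, the
conventions, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## Feature model

A scan is a 3D scalar volume (ADC in 10⁻⁶ mm²/s) with a binary tumor mask
on the same grid. Features are computed on the original volume and on its
gradient-magnitude image (spacing-aware central differences on the full
grid, one-sided at borders; computing on the full grid avoids stencil
artifacts at the ROI edge). Both images are discretized inside the mask
with a fixed bin width of 50 intensity units anchored at the ROI minimum:

    level(v) = floor((v − min_ROI) / 50) + 1.

`Ng` is the highest assigned level; with width-based binning, interior
levels can be unoccupied, and the matrix builders tolerate such gaps.
Min-anchoring is the common convention for fixed-bin-width discretization
of ADC maps.

Seven feature families are computed:

* **first-order** — moments of the masked intensities. Kurtosis uses the
  non-excess (Pearson) convention m₄/m₂², so a normal sample gives ≈ 3;
  the ±3 offset changes delta magnitudes but no group comparison.
  Intensity entropy/uniformity use the same bin-width-50 histogram as the
  texture discretization.
* **shape** — marching-cubes mesh surface area and volume of the mask,
  their ratio, and principal axis lengths from the covariance of the
  foreground voxel physical coordinates.
* **GLCM, GLRLM, GLSZM, GLDZM, NGTDM** — the five standard gray-level
  texture matrices, built over the 26-neighborhood system (13 unique 3D
  directions), restricted to in-mask voxels.

Aggregation merges counts across all 13 directions into a single matrix
before feature computation (the alternative, per-direction averaging, is
not offered): merging is deterministic, keeps the matrix invariants exact
integers, and makes the brute-force test oracles trivial to state. The
GLCM distance is 1 voxel by default (configurable). Zones and neighbor
systems are 26-connected throughout. All entropies are base 2 with
0·log 0 ≡ 0 and no epsilon inside logarithms. Undefined features (zero
variance, single gray level, a single isolated voxel's GLCM) are explicit
NaNs, propagated as missing downstream — never silently zero.

Every extraction reports a guaranteed panel of 14 features (shape
surface-to-volume ratio and minor axis, intensity kurtosis, zone
percentage, zone entropy, small-area low-gray-level emphasis, short-run
emphasis, GLCM inverse variance, information measure of correlation 1 and
inverse difference normalized on the original image; kurtosis, short-run
emphasis, run entropy and inverse difference normalized on the gradient
image), each tagged with its IBSI permanent identifier where defined. The
full roster is ~192 features; family enumerations differ slightly between
radiomics implementations and this package documents its own roster
rather than matching any particular count.

### Numerical choices in the shape family

Marching cubes on a raw binary mask overestimates the surface of smooth
shapes by ~9 % (staircase effect), so the mask is anti-aliased with a
Gaussian of 0.8 voxels before meshing; a digitized ball of radius 10 mm
then reports A/V within ~2 % of the analytic 3/r. Axis lengths are
calibrated to the equivalent uniform ellipsoid, `2·sqrt(5·λ)` for each
covariance eigenvalue λ, so a ball of radius r reports a diameter of 2r
and an ellipsoid reports its true axis diameters. This differs from the
Gaussian-calibrated `4·sqrt(λ)` convention by the constant factor
√5/2 ≈ 1.118, which cancels in every relative change and therefore in the
whole delta analysis. Degenerate meshes (single-voxel masks) fall back to
voxel-face surface and voxel volume with a warning.

## Delta pipeline

The delta feature at follow-up tᵢ is Δf = (f_tᵢ − f_t₀)/f_t₀ —
dimensionless and scale-free; zero or undefined baselines make the entry
missing. Cohort-level deltas are Z-scored per feature (sample SD, n−1)
before selection and clustering; constant or under-observed columns are
dropped with a log entry.

Selection is two-stage with PFS (days) as the target:

1. keep features with |Pearson r| ≥ 0.2 against PFS, pairwise-complete,
   after dropping features missing in > 30 % of patients. The absolute
   value is deliberate: a signed rule would discard all negatively
   predictive features, contradicting the retained features with negative
   group means. The threshold is inclusive (a feature at exactly 0.2 is
   retained; a 10⁻¹² guard absorbs correlation round-off).
2. greedy multicollinearity pruning: order by descending |r| to the
   target (ties broken lexicographically); drop any feature correlated at
   |r| > 0.85 with an already-kept one. The survivor of a correlated pair
   is thus the member more predictive of PFS. The result has all pairwise
   |r| ≤ 0.85 and the operation is idempotent.

Selection is pooled over arms and response groups.

## Cohort analysis

Patients are clustered on the normalized, selected deltas with Ward's
minimum-variance criterion on Euclidean distances, tree cut at k = 2;
missing entries are imputed with the column median first (Ward needs
complete vectors). Cluster 1 is defined as the cluster with shorter mean
observed PFS — the non-responder-enriched side. Group differences use
Welch two-sample t-tests (two-sided, α = 0.05): group sizes here are
heavily unbalanced (e.g. 120 vs 10), where the unequal-variance test is
the defensible default. Families for Holm's step-down correction are the
features tested within one grouping analysis. Two dichotomizations are
built in: PFS strictly > 365 days versus ≤ 365, and progressive disease
versus partial-response-or-stable-disease. Survival uses the
Kaplan–Meier product-limit estimator (median = first time S(t) ≤ 0.5,
undefined if never reached) and the two-group log-rank test with
Breslow-style handling of ties, both via `lifelines`.

## Synthetic cohort generator

The generator exists so that the entire stack — extraction included — can
be validated end to end: treatment effects are implanted in *image
space*, never in feature space, so a recovery test exercises every stage.

**Phantom.** An ellipsoidal low-ADC lesion (default radius 20 mm, mean
900 ± 150 ×10⁻⁶ mm²/s) with spatially correlated Gaussian texture
(correlation length 4 mm; Gaussian-filtered white noise rescaled to the
exact target moments) inside a uniform higher-ADC background
(1500 ×10⁻⁶ mm²/s). The default grid is 104×136 in-plane at 3.3 mm with
25 slices at 6 mm. No intensity statistics of real tumor ADC ROIs back
these defaults; they are literature-typical values and flagged as such.

**Response mechanisms.** Responders receive randomly placed spherical
patches (radius 5 mm) of ADC elevated 40 % of the way toward background,
covering a set fraction of tumor voxels — the image correlate of
patchwise cell death increasing local diffusivity. This fragments the
texture: short-run emphasis and zone percentage rise, inverse difference
normalized falls. Non-responders receive in-mask smoothing (normalized
convolution, 8 mm kernel, so the tumor/background boundary does not
bleed into the lesion) plus isotropic growth — uniformly restricted
diffusion over a denser, larger tumor — moving the same features the
opposite way. A small correlated rescan noise (SD 10) keeps repeat scans
from being bit-identical. Default profiles: strong responder
(fraction 0.35), mild responder (0.20), mild non-responder
(homogenization 0.6, growth 1.03), strong non-responder (homogenization
1.0, growth 1.10). These magnitudes are calibration constants of the
generator chosen so pooled mean deltas land near the scale typical of
such cohorts (zone-percentage change ≈ +0.2 in responders vs ≈ −0.1 in
non-responders); they are not measured values.

**Cohort structure.** 130 patients: 64 in a TKI-like arm (follow-up
scans at days 7 and 14) and 66 in a chemotherapy-like arm (day 1, with a
17-patient subset re-scanned at day 7), response classes 40 PR / 80 SD /
10 PD distributed over arms as 32/27/5 and 8/53/5. Effects ramp in with
a saturating factor 1 − exp(−day/1.5 d), so a day-1 scan carries roughly
half the asymptotic effect — early follow-ups are weaker, later ones
near-asymptotic.

**Outcome model.** A latent outcome group drives both the image response
and survival: the *short-PFS* group (exponential median 180 d) holds all
10 PD patients plus a 52.5 % fraction of SD patients programmed as mild
non-responders (~52 patients, 40 % of the cohort); the *long-PFS* group
(median 363 d) holds PR and the remaining SD. This 40/60 latent split is
the design choice that lets a two-cluster cut have both the composition
(a 40 % cluster holding ≥ 9/10 PD patients) and the survival separation
a cohort of this size can actually exhibit: with only the 10 PD patients
against 120 others, a log-rank test at hazard ratio ~2 has ≈ 50 % power
and no faithful simulation could separate reliably. OS is PFS plus an
exponential tail (median 100 d). Censoring is independent uniform,
calibrated so the expected censored fraction matches the configuration
(15 % PFS, 30 % OS) — non-informative by construction, so Kaplan–Meier
stays consistent. All randomness derives from one master seed through
`SeedSequence([master, patient_index, stage])` with documented stage
codes.

## What the validation shows — and does not

The test suite establishes: exact element-level agreement of all five
matrix builders with brute-force enumeration on random small ROIs;
analytic closed forms (constant, single-voxel, all-distinct textures;
digitized-ball shape limits); algebraic identities of the delta/Z-score/
Holm/KM stack; strict sign recovery of both response mechanisms over
seed batteries; end-to-end recovery of the programmed cluster structure,
PD capture, survival separation and KM medians on replicate cohorts
(run on a reduced 64×64×16 grid with 18 mm phantoms — the problem size
chosen for the replicate batteries); and type-I calibration of the
testing stack under a null generator.

It does not show anything about real lung-tumor ADC data: the phantoms
have no MRI physics (no noise spectra, EPI distortion or partial-volume
effects), no registration error between timepoints, no segmentation
variability, and a single lesion per patient with an analytically clean
boundary. The generator's effect sizes are calibrated, not measured, so
passing recovery tests demonstrate that the pipeline detects effects *of
the programmed kind and size*, not that such effects exist clinically.

## Known limitations

* No resampling/interpolation harmonization, wavelet/LoG filtered
  images, or 2D per-slice aggregation modes.
* Per-direction texture aggregation is not implemented (merged only).
* Survival modeling is descriptive (KM + log-rank); no Cox regression or
  hazard ratios.
* The follow-up ROI is an explicit input per timepoint; the package
  takes no position on re-segmentation versus propagation.
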