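# deltarad

Delta-radiomics analysis of longitudinal diffusion-MRI ADC maps.

Morphological response assessment in solid tumors (RECIST on follow-up
CT) takes months to become conclusive. Diffusion-weighted MRI measures
water diffusivity — the apparent diffusion coefficient (ADC) — which
changes within days of effective treatment as cell death locally
*sparsifies* tissue. `deltarad` implements the analysis pipeline for
detecting that change: it quantifies a tumor ROI with radiomics texture,
intensity and shape features, tracks each feature's relative change
between baseline and early follow-up scans, and tests whether those
changes stratify patients by response and survival. It is written for
imaging scientists who have per-patient ADC volumes with tumor masks
(NIfTI) and a clinical table, and for methodologists who want a fully
testable radiomics stack with no opaque dependencies.

## The model

For a feature f measured at baseline t₀ and follow-up tᵢ, the
delta-radiomics feature is the relative change

    Δf_tᵢ = (f_tᵢ − f_t₀) / f_t₀ .

Features are computed on the masked ADC volume and its
gradient-magnitude image, discretized with a fixed bin width of 50
(10⁻⁶ mm²/s), over seven families: first-order intensity statistics,
mesh-based shape descriptors, and the five gray-level texture matrices
(GLCM, GLRLM, GLSZM, GLDZM, NGTDM) built over all 13 unique 3D
directions, restricted to the mask. Cohort deltas are Z-scored and
filtered in two stages against progression-free survival (keep
|r_p| ≥ 0.2, then greedily prune pairs with |r_p| > 0.85). The selected
features feed Ward minimum-variance clustering (k = 2), Welch t-tests
with Holm step-down correction between outcome groups (PFS > 365 d vs
≤ 365 d; progressive disease vs partial response/stable disease), and
Kaplan–Meier / log-rank comparison of the two clusters.

Heterogeneity features carry the signal: short-run emphasis (SRE, IBSI
22OV) and zone percentage (ZP, P30P) rise when treatment fragments the
diffusion-restricted tissue, while inverse difference normalized (IDN,
NDRX) — a homogeneity measure — falls; non-responding tumors move the
opposite way.

A synthetic-cohort generator produces complete longitudinal phantom
cohorts (ellipsoidal low-ADC lesions with correlated texture, response
implanted in image space, exponential survival with censoring) so that
every pipeline stage is testable without any patient data.

## Worked example

```python
import deltarad as dr
from deltarad.model import DeltaRadiomicsModel

# a full synthetic cohort: 130 patients, arms 64/66, classes 40/80/10,
# on a reduced 64x64x16 grid (seconds per patient-scan to extract)
cfg = dr.reduced_cohort_config(master_seed=1)
features, clinical = dr.simulate_cohort_features(cfg)

model = DeltaRadiomicsModel.from_features(features, clinical, timepoint="last")
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Delta-radiomics cohort analysis
==============================================
patients: 130   follow-up: last
features: 192 extracted, 116 past |r|>=0.2 to PFS, 18 after collinearity pruning
...
Ward clusters: cluster 1: n=52, cluster 2: n=78
PFS log-rank p = 2.2e-06; KM medians: cluster 1: 119 d, cluster 2: 364 d
OS log-rank p = 1.63e-05; KM medians: cluster 1: 283 d, cluster 2: 491 d

group test PFS > 365 d vs <= 365 d: 18/18 features at Holm p < 0.05
```

Cluster 1 (the non-responder-enriched side, 40 % of patients) holds all
10 programmed progressive-disease patients and has markedly shorter
progression-free survival; the KM medians approach the programmed group
medians of 180 and 363 days. `results.plot_heatmap()` draws the
patients × features cluster heatmap, `results.plot_km("pfs")` the
survival curves.

The same analysis runs from the shell on a cohort directory of
`<patient>_<timepoint>_adc.nii.gz` / `<patient>_<timepoint>_mask.nii.gz`
pairs (timepoints `BL`, `FU1`, `FU2`, ...) plus a `clinical.csv` with
columns `patient_id, arm, recist, pfs_days, pfs_event, os_days,
os_event`:

```
deltarad simulate --out cohort/ --seed 1
deltarad extract  --cohort cohort/ --out features.csv
deltarad analyze  --features features.csv --clinical cohort/clinical.csv --out analysis/
```

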