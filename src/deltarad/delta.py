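"""Delta-radiomics: longitudinal relative change and feature selection.

The delta feature between baseline t0 and follow-up ti is the relative
change

    delta_f = (f_ti - f_t0) / f_t0,

which is dimensionless and scale-free.  Features with a zero or undefined
baseline are missing (NaN) at that patient.  Across a cohort the deltas
form a patients x features matrix which is Z-score normalized columnwise
before selection and clustering.

Selection is two-stage, with progression-free survival (PFS, days) as
the target:

1. keep features with |Pearson r(delta_f, PFS)| >= 0.2 (pairwise-complete;
   the threshold is inclusive — r exactly at the threshold is retained);
2. greedily remove multicollinear features until all pairwise |r| <= 0.85,
   keeping the member of each correlated pair with the higher |r| to the
   target.

The absolute value in stage 1 is deliberate: a signed rule would discard
every negatively predictive feature, and several retained features in the
panel have negative group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, SelectionError
from .features import FeatureVector

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the two-stage feature selection."""

    target_r_min: float = 0.2
    collinearity_r_max: float = 0.85
    max_missing_fraction: float = 0.30

    def __post_init__(self) -> None:
        for name in ("target_r_min", "collinearity_r_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")


@dataclass
class DeltaMatrix:
    """Patients x features matrix of relative feature changes.

    Wraps a pandas DataFrame (rows = patient ids, columns = feature keys);
    `normalized` records whether columns have been Z-scored and
    `timepoint` labels the follow-up the deltas refer to (e.g. "FU2").
    """

    data: pd.DataFrame
    timepoint: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise SchemaError("duplicate patient ids in delta matrix")
        if self.data.columns.duplicated().any():
            raise SchemaError("duplicate feature keys in delta matrix")

    @property
    def patients(self) -> list:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="patient_id")


def delta_features(baseline: FeatureVector, followup: FeatureVector) -> FeatureVector:
    """Relative change per feature key.

    Keys with a baseline of exactly 0 or an undefined baseline/follow-up
    value are reported as NaN (missing), never as +/-inf.
    """
    shared = baseline.keys() & followup.keys()
    if not shared:
        raise SchemaError("baseline and follow-up share no feature keys")
    out = {}
    for k in (k for k in baseline if k in shared):
        f0, f1 = baseline[k], followup[k]
        if f0 == 0 or not np.isfinite(f0) or not np.isfinite(f1):
            out[k] = float("nan")
        else:
            out[k] = (f1 - f0) / f0
    return FeatureVector(out)


def build_delta_matrix(
    baselines: dict[str, FeatureVector],
    followups: dict[str, FeatureVector],
    timepoint: str = "",
) -> DeltaMatrix:
    """Assemble per-patient delta vectors into a DeltaMatrix."""
    if set(baselines) != set(followups):
        raise SchemaError("baseline and follow-up patient sets differ")
    rows = {pid: dict(delta_features(baselines[pid], followups[pid])) for pid in sorted(baselines)}
    return DeltaMatrix(pd.DataFrame.from_dict(rows, orient="index"), timepoint=timepoint)


def zscore_normalize(m: DeltaMatrix) -> DeltaMatrix:
    """Columnwise (x - mean)/sd with sample SD (ddof=1) over non-missing
    entries.  Columns with < 2 non-missing values or zero SD are dropped
    (logged)."""
    df = m.data
    keep = {}
    dropped = []
    for col in df.columns:
        x = df[col]
        n = x.notna().sum()
        sd = x.std(ddof=1)
        if n < 2 or not np.isfinite(sd) or sd == 0:
            dropped.append(col)
            continue
        keep[col] = (x - x.mean()) / sd
    if dropped:
        logger.warning("z-score dropped %d constant/under-observed columns", len(dropped))
    return DeltaMatrix(pd.DataFrame(keep, index=df.index), timepoint=m.timepoint, normalized=True)


def select_by_target_correlation(
    m: DeltaMatrix,
    target: pd.Series,
    cfg: SelectionConfig | None = None,
) -> list[tuple[str, float]]:
    """Stage-1 selection: keep features with |r_p| >= cfg.target_r_min
    against the target (PFS days), pairwise-complete.

    Features missing in more than `cfg.max_missing_fraction` of patients
    are dropped beforehand.  Returns (key, r) pairs in column order.
    """
    cfg = cfg or SelectionConfig()
    target = target.reindex(m.data.index)
    if target.notna().sum() < 3:
        raise SelectionError("target available for fewer than 3 patients")
    if target.std(ddof=1) == 0 or not np.isfinite(target.std(ddof=1)):
        raise SelectionError("zero-variance selection target")
    kept = []
    for col in m.data.columns:
        x = m.data[col]
        if x.isna().mean() > cfg.max_missing_fraction:
            continue
        both = x.notna() & target.notna()
        if both.sum() < 3 or x[both].std(ddof=1) == 0:
            continue
        r = float(np.corrcoef(x[both], target[both])[0, 1])
        # inclusive threshold with a guard for correlation round-off, so a
        # feature at exactly the threshold is retained
        if abs(r) >= cfg.target_r_min - 1e-12:
            kept.append((col, r))
    return kept


def prune_multicollinear(
    m: DeltaMatrix,
    keys: list[tuple[str, float]] | list[str],
    target: pd.Series,
    cfg: SelectionConfig | None = None,
) -> list[str]:
    """Stage-2 greedy multicollinearity pruning.

    Keys are ordered by descending |r(., target)| (ties broken by
    lexicographic key); walking that order, any later key correlated with
    an already-kept key at |r| > cfg.collinearity_r_max is dropped, so the
    survivor of each correlated pair is the member more correlated with
    the target.  The result has all pairwise |r| <= the threshold and the
    operation is idempotent.
    """
    cfg = cfg or SelectionConfig()
    target = target.reindex(m.data.index)
    if keys and isinstance(keys[0], tuple):
        scored = list(keys)
    else:
        scored = []
        for k in keys:
            x = m.data[k]
            both = x.notna() & target.notna()
            scored.append((k, float(np.corrcoef(x[both], target[both])[0, 1])))
    order = sorted(scored, key=lambda kr: (-abs(kr[1]), kr[0]))
    kept: list[str] = []
    for key, _ in order:
        ok = True
        for other in kept:
            both = m.data[key].notna() & m.data[other].notna()
            if both.sum() < 3:
                continue
            r = abs(float(np.corrcoef(m.data[key][both], m.data[other][both])[0, 1]))
            if r > cfg.collinearity_r_max:
                ok = False
                break
        if ok:
            kept.append(key)
    # restore original column order for stable downstream layout
    colpos = {c: i for i, c in enumerate(m.data.columns)}
    return sorted(kept, key=lambda k: colpos[k])


def select_features(
    m: DeltaMatrix,
    target: pd.Series,
    cfg: SelectionConfig | None = None,
) -> dict:
    """Run both selection stages; returns a report dict with the surviving
    keys, their target correlations, and what was dropped at each stage."""
    cfg = cfg or SelectionConfig()
    stage1 = select_by_target_correlation(m, target, cfg)
    survivors = prune_multicollinear(m, stage1, target, cfg)
    r_by_key = dict(stage1)
    return {
        "selected": survivors,
        "target_r": {k: r_by_key[k] for k in survivors},
        "stage1_kept": [k for k, _ in stage1],
        "stage1_dropped": [c for c in m.data.columns if c not in r_by_key],
        "stage2_dropped": [k for k, _ in stage1 if k not in survivors],
    }
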