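"""Cohort-level statistics: clustering, group tests, survival.

Patients are clustered on their normalized delta features with Ward's
minimum-variance criterion (Euclidean distances, tree cut at k=2).
Group differences in feature change are assessed with Welch two-sample
t-tests (the defensible default under the heavily unbalanced group sizes
of a PD-versus-rest comparison), corrected with Holm's step-down method
within the tested family.  Survival separation between clusters uses
Kaplan-Meier estimates and the two-group log-rank test with right
censoring (Breslow-style tie handling in the expected counts).

Grouping conventions: PFS dichotomized at strictly > 365 days; response
dichotomized as PD versus PR-or-SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .delta import DeltaMatrix
from .errors import ConfigError, SchemaError

ARMS = ("TKI", "PBC")
RECIST_CLASSES = ("PR", "SD", "PD")

COHORT_COLUMNS = ("patient_id", "arm", "recist", "pfs_days", "pfs_event", "os_days", "os_event")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a clinical table to the cohort schema.

    Columns: patient_id, arm (TKI|PBC), recist (PR|SD|PD), pfs_days,
    pfs_event, os_days, os_event.  Ids must be unique, event flags binary,
    times non-negative.
    """
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"cohort table missing columns: {sorted(missing)}")
    t = table.copy()
    if t["patient_id"].duplicated().any():
        raise SchemaError("duplicate patient ids in cohort table")
    if not set(t["arm"]).issubset(ARMS):
        raise SchemaError(f"arm values must be in {ARMS}")
    if not set(t["recist"]).issubset(RECIST_CLASSES):
        raise SchemaError(f"recist values must be in {RECIST_CLASSES}")
    for col in ("pfs_event", "os_event"):
        if not set(t[col].astype(int)).issubset({0, 1}):
            raise SchemaError(f"{col} must be binary")
        t[col] = t[col].astype(int)
    for col in ("pfs_days", "os_days"):
        if (t[col] < 0).any():
            raise SchemaError(f"{col} must be non-negative")
    return t.set_index("patient_id", drop=False)


@dataclass(frozen=True)
class GroupingConfig:
    """How patients are dichotomized for the group tests."""

    pfs_cut_days: int = 365
    pd_classes: tuple[str, ...] = ("PD",)

    def __post_init__(self) -> None:
        if self.pfs_cut_days <= 0:
            raise ConfigError("pfs_cut_days must be positive")

    def pfs_groups(self, table: pd.DataFrame) -> pd.Series:
        """True for long PFS (strictly > cut)."""
        return table["pfs_days"] > self.pfs_cut_days

    def response_groups(self, table: pd.DataFrame) -> pd.Series:
        """True for responders (PR or SD), False for PD."""
        return ~table["recist"].isin(self.pd_classes)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    """Two-cluster Ward partition of the patients."""

    linkage: np.ndarray
    labels: pd.Series  # patient -> {1, 2}
    feature_order: list[str]
    imputed: bool

    @property
    def sizes(self) -> dict[int, int]:
        return self.labels.value_counts().to_dict()


def ward_cluster(m: DeltaMatrix, k: int = 2) -> ClusterResult:
    """Agglomerative Ward clustering of patients on Euclidean distances.

    Missing entries are imputed with the column median first (Ward needs
    complete vectors).  The tree is cut into `k` clusters; the result is
    deterministic for a given input order (scipy breaks merge-height ties
    by observation index, lower index first).  The reported feature order
    is the leaf order of a Ward dendrogram over feature columns, for
    heatmap display.
    """
    if not m.normalized:
        raise ValueError("ward_cluster expects a normalized delta matrix")
    if k < 1 or m.data.shape[0] < 2 * k:
        raise ConfigError(f"need >= {2 * k} patients for k={k} clusters")
    df = m.data
    imputed = bool(df.isna().any().any())
    if imputed:
        df = df.fillna(df.median())
    x = df.to_numpy(dtype=np.float64)
    link = hierarchy.linkage(x, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    if df.shape[1] >= 2:
        flink = hierarchy.linkage(x.T, method="ward", metric="euclidean")
        forder = [df.columns[i] for i in hierarchy.leaves_list(flink)]
    else:
        forder = list(df.columns)
    return ClusterResult(
        linkage=link,
        labels=pd.Series(labels, index=df.index, name="cluster"),
        feature_order=forder,
        imputed=imputed,
    )


# ---------------------------------------------------------------------------
# group tests


@dataclass
class TestResult:
    """Welch t-test of one feature between two patient groups."""

    feature: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    p_holm: float = float("nan")
    significant: bool = False


def group_ttest(m: DeltaMatrix, groups: pd.Series) -> list[TestResult]:
    """Welch two-sample t-test per feature between groups True/False.

    NaN entries are dropped per feature; features with < 2 observations in
    either group are skipped.  An entirely empty group raises.
    """
    groups = groups.reindex(m.data.index)
    n_true = int((groups == True).sum())  # noqa: E712 - may contain NaN
    n_false = int((groups == False).sum())  # noqa: E712
    if n_true == 0 or n_false == 0:
        raise ValueError(
            f"group test needs both groups non-empty (sizes {n_true} vs {n_false} "
            f"for grouping {groups.name or 'unnamed'})"
        )
    out = []
    for col in m.data.columns:
        x = m.data[col]
        a = x[(groups == True) & x.notna()]  # noqa: E712
        b = x[(groups == False) & x.notna()]  # noqa: E712
        if len(a) < 2 or len(b) < 2:
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                continue  # constant feature carries no test
            t_stat, p = float("inf"), 0.0
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        out.append(
            TestResult(
                feature=col,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                n_a=len(a),
                n_b=len(b),
                t=float(t_stat),
                p=float(p),
            )
        )
    return out


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, original order preserved.

    p'_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending order.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=0.05, method="holm")[1]


def apply_holm(results: list[TestResult], alpha: float = 0.05) -> list[TestResult]:
    """Attach Holm-adjusted p-values and significance flags to a family of
    test results (the family is exactly the list passed in)."""
    if not results:
        return results
    adj = holm_adjust([r.p for r in results])
    for r, pa in zip(results, adj):
        r.p_holm = float(pa)
        r.significant = bool(pa < alpha)
    return results


def tests_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "mean_group_a": [r.mean_a for r in results],
            "mean_group_b": [r.mean_b for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
            "p_holm": [r.p_holm for r in results],
            "significant": [r.significant for r in results],
        }
    )


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate with right censoring."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # inf if S never reaches 0.5
    n: int
    n_events: int

    @property
    def median_defined(self) -> bool:
        return math.isfinite(self.median)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate; median is the first time S(t) <= 0.5
    (infinite, flagged undefined, if the curve never reaches 0.5)."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_["KM_estimate"]
    grid = sf.index.to_numpy(dtype=np.float64)
    surv = sf.to_numpy(dtype=np.float64)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).fillna(0).to_numpy(dtype=np.int64)
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        median=float(kmf.median_survival_time_),
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) with right censoring.

    Returns (statistic, p).  A group with zero observed events is allowed
    (the statistic is still defined); empty groups are not.
    """
    ta = np.asarray(times_a, dtype=np.float64)
    tb = np.asarray(times_b, dtype=np.float64)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(ta, tb, event_observed_A=np.asarray(events_a), event_observed_B=np.asarray(events_b))
    return float(res.test_statistic), float(res.p_value)
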