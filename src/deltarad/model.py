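"""End-to-end delta-radiomics analysis as a model/results pair.

`DeltaRadiomicsModel` holds a delta-feature matrix and a clinical table;
`fit()` runs normalization, two-stage feature selection against PFS,
Ward clustering of patients, Holm-corrected Welch group tests (PFS-split
and response-split), and Kaplan-Meier / log-rank survival comparison of
the two clusters, returning a `DeltaRadiomicsResults` with a `summary()`
table and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    ClusterResult,
    GroupingConfig,
    SurvivalCurve,
    TestResult,
    apply_holm,
    group_ttest,
    km_estimate,
    logrank_test,
    tests_to_frame,
    validate_cohort_table,
    ward_cluster,
)
from .delta import DeltaMatrix, SelectionConfig, select_features, zscore_normalize
from .errors import SelectionError
from .features import FeatureVector
from .delta import build_delta_matrix


def delta_matrix_from_features(
    features: dict[str, dict[str, FeatureVector]],
    timepoint: str = "last",
) -> DeltaMatrix:
    """Build a DeltaMatrix from per-patient, per-timepoint feature vectors.

    `timepoint` is a follow-up label ("FU1", "FU2", ... — patients lacking
    it are dropped) or "last" for each patient's latest follow-up.
    """
    baselines, followups = {}, {}
    for pid, by_tp in features.items():
        if "BL" not in by_tp:
            continue
        if timepoint == "last":
            fus = sorted(tp for tp in by_tp if tp.startswith("FU"))
            if not fus:
                continue
            tp = fus[-1]
        else:
            if timepoint not in by_tp:
                continue
            tp = timepoint
        baselines[pid] = by_tp["BL"]
        followups[pid] = by_tp[tp]
    if not baselines:
        raise ValueError(f"no patient has both BL and {timepoint!r}")
    return build_delta_matrix(baselines, followups, timepoint=timepoint)


@dataclass
class DeltaRadiomicsResults:
    """Fitted artifacts of a delta-radiomics cohort analysis."""

    model: "DeltaRadiomicsModel"
    delta_normalized: DeltaMatrix
    selection: dict
    clusters: ClusterResult
    tests_pfs: list[TestResult]
    tests_response: list[TestResult]
    survival: dict[str, dict[int, SurvivalCurve]]
    logrank: dict[str, tuple[float, float]]

    @property
    def selected_features(self) -> list[str]:
        return self.selection["selected"]

    @property
    def cluster_labels(self) -> pd.Series:
        return self.clusters.labels

    @property
    def tests(self) -> pd.DataFrame:
        """All group tests as one tidy frame (grouping column included)."""
        frames = []
        for name, res in (("pfs_gt365", self.tests_pfs), ("response_pd", self.tests_response)):
            f = tests_to_frame(res)
            f.insert(0, "grouping", name)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def survival_summary(self) -> dict:
        out = {}
        for endpoint, curves in self.survival.items():
            stat, p = self.logrank[endpoint]
            out[endpoint] = {
                "logrank_statistic": stat,
                "logrank_p": p,
                "medians": {int(c): curve.median for c, curve in curves.items()},
                "n": {int(c): curve.n for c, curve in curves.items()},
            }
        return out

    def summary(self) -> str:
        lines = []
        n = self.delta_normalized.data.shape[0]
        lines.append("Delta-radiomics cohort analysis")
        lines.append("=" * 46)
        lines.append(f"patients: {n}   follow-up: {self.delta_normalized.timepoint or 'last'}")
        lines.append(
            f"features: {len(self.model.delta.features)} extracted, "
            f"{len(self.selection['stage1_kept'])} past |r|>={self.model.selection_config.target_r_min} "
            f"to PFS, {len(self.selected_features)} after collinearity pruning"
        )
        lines.append("")
        lines.append("selected features (r to PFS):")
        for k in self.selected_features:
            lines.append(f"  {k:55s} r={self.selection['target_r'][k]:+.2f}")
        sizes = self.clusters.sizes
        lines.append("")
        lines.append(f"Ward clusters: " + ", ".join(f"cluster {c}: n={sizes[c]}" for c in sorted(sizes)))
        for endpoint in self.survival:
            s = self.survival_summary()[endpoint]
            med = ", ".join(
                f"cluster {c}: {m:.0f} d" if np.isfinite(m) else f"cluster {c}: not reached"
                for c, m in s["medians"].items()
            )
            lines.append(f"{endpoint.upper()} log-rank p = {s['logrank_p']:.3g}; KM medians: {med}")
        lines.append("")
        for name, res in (("PFS > 365 d vs <= 365 d", self.tests_pfs), ("PR/SD vs PD", self.tests_response)):
            sig = [r for r in res if r.significant]
            lines.append(f"group test {name}: {len(sig)}/{len(res)} features at Holm p < 0.05")
            for r in sig:
                lines.append(
                    f"  {r.feature:55s} mu_a={r.mean_a:+.3f} mu_b={r.mean_b:+.3f} p_holm={r.p_holm:.3g}"
                )
        return "\n".join(lines)

    # -- plots -------------------------------------------------------------

    def plot_heatmap(self, ax=None):
        """Patients x selected-features heatmap, rows ordered by cluster."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 6))
        df = self.delta_normalized.data[self.clusters.feature_order]
        order = self.clusters.labels.sort_values(kind="stable").index
        data = df.loc[order].to_numpy()
        im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
        boundary = int((self.clusters.labels.loc[order] == sorted(self.clusters.sizes)[0]).sum())
        ax.axhline(boundary - 0.5, color="k", lw=2)
        ax.set_xticks(range(df.shape[1]))
        ax.set_xticklabels([c.split(".", 1)[-1] for c in df.columns], rotation=90, fontsize=7)
        ax.set_ylabel("patients (grouped by cluster)")
        ax.figure.colorbar(im, ax=ax, label="z-scored delta feature")
        return ax

    def plot_km(self, endpoint: str = "pfs", ax=None):
        """Kaplan-Meier curves of the two clusters for an endpoint."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c, curve in sorted(self.survival[endpoint].items()):
            ax.step(curve.times, curve.survival, where="post", label=f"cluster {c} (n={curve.n})")
        stat, p = self.logrank[endpoint]
        ax.set_xlabel("days")
        ax.set_ylabel(f"S(t), {endpoint.upper()}")
        ax.set_ylim(0, 1.02)
        ax.legend(title=f"log-rank p = {p:.3g}")
        return ax


class DeltaRadiomicsModel:
    """Cohort-level delta-radiomics analysis.

    Parameters
    ----------
    delta : DeltaMatrix
        Patients x features relative changes (unnormalized; `fit`
        Z-scores internally).
    clinical : DataFrame
        Cohort table with patient_id, arm, recist, pfs_days, pfs_event,
        os_days, os_event.
    selection, grouping : optional configs
        Selection thresholds and dichotomization rules.
    """

    def __init__(
        self,
        delta: DeltaMatrix,
        clinical: pd.DataFrame,
        selection: SelectionConfig | None = None,
        grouping: GroupingConfig | None = None,
    ):
        clinical = validate_cohort_table(clinical)
        common = [p for p in delta.data.index if p in clinical.index]
        if len(common) < 4:
            raise ValueError("need >= 4 patients present in both delta matrix and clinical table")
        self.delta = DeltaMatrix(delta.data.loc[common], timepoint=delta.timepoint, normalized=delta.normalized)
        self.clinical = clinical.loc[common]
        self.selection_config = selection or SelectionConfig()
        self.grouping_config = grouping or GroupingConfig()

    @classmethod
    def from_features(
        cls,
        features: dict[str, dict[str, FeatureVector]],
        clinical: pd.DataFrame,
        timepoint: str = "last",
        **kwargs,
    ) -> "DeltaRadiomicsModel":
        return cls(delta_matrix_from_features(features, timepoint), clinical, **kwargs)

    def fit(self, n_clusters: int = 2) -> DeltaRadiomicsResults:
        """Run selection, clustering, group tests and survival comparison."""
        normalized = self.delta if self.delta.normalized else zscore_normalize(self.delta)
        target = self.clinical["pfs_days"]
        selection = select_features(normalized, target, self.selection_config)
        selected = selection["selected"]
        if not selected:
            raise SelectionError("no feature passes the PFS-correlation filter; nothing to cluster")
        sub = DeltaMatrix(normalized.data[selected], timepoint=normalized.timepoint, normalized=True)
        clusters = ward_cluster(sub, k=n_clusters)
        # name cluster 1 = shorter observed PFS (the non-responder-enriched side)
        mean_pfs = self.clinical["pfs_days"].groupby(clusters.labels).mean()
        order = list(mean_pfs.sort_values().index)
        relabel = {old: new + 1 for new, old in enumerate(order)}
        clusters.labels = clusters.labels.map(relabel)

        raw_selected = DeltaMatrix(self.delta.data[selected], timepoint=self.delta.timepoint)
        tests_pfs = apply_holm(group_ttest(raw_selected, self.grouping_config.pfs_groups(self.clinical)))
        tests_resp = apply_holm(group_ttest(raw_selected, self.grouping_config.response_groups(self.clinical)))

        survival: dict[str, dict[int, SurvivalCurve]] = {}
        logrank: dict[str, tuple[float, float]] = {}
        for endpoint in ("pfs", "os"):
            tcol, ecol = f"{endpoint}_days", f"{endpoint}_event"
            curves = {}
            groups = {}
            for c in sorted(clusters.labels.unique()):
                pids = clusters.labels[clusters.labels == c].index
                t = self.clinical.loc[pids, tcol].to_numpy()
                e = self.clinical.loc[pids, ecol].to_numpy()
                curves[int(c)] = km_estimate(t, e)
                groups[int(c)] = (t, e)
            survival[endpoint] = curves
            if len(groups) == 2:
                (ta, ea), (tb, eb) = (groups[c] for c in sorted(groups))
                logrank[endpoint] = logrank_test(ta, ea, tb, eb)
        return DeltaRadiomicsResults(
            model=self,
            delta_normalized=DeltaMatrix(normalized.data[selected], timepoint=normalized.timepoint, normalized=True),
            selection=selection,
            clusters=clusters,
            tests_pfs=tests_pfs,
            tests_response=tests_resp,
            survival=survival,
            logrank=logrank,
        )
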