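"""Clustering, group tests, Holm correction, Kaplan-Meier and log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltarad.cohort import (
    GroupingConfig,
    group_ttest,
    holm_adjust,
    km_estimate,
    logrank_test,
    validate_cohort_table,
    ward_cluster,
)
from deltarad.delta import DeltaMatrix
from deltarad.errors import ConfigError, SchemaError

from _oracles import brute_holm, brute_km, brute_logrank


def _dm(arr, normalized=True, index=None, cols=None):
    arr = np.asarray(arr, dtype=float)
    index = index if index is not None else [f"p{i}" for i in range(arr.shape[0])]
    cols = cols if cols is not None else [f"f{j}" for j in range(arr.shape[1])]
    return DeltaMatrix(pd.DataFrame(arr, index=index, columns=cols), normalized=normalized)


class TestWardCluster:
    def test_separable_clouds_recovered_exactly(self, rng):
        a = rng.normal(-5, 1, size=(40, 14))
        b = rng.normal(5, 1, size=(60, 14))
        m = _dm(np.vstack([a, b]))
        res = ward_cluster(m, k=2)
        la = res.labels.iloc[:40]
        lb = res.labels.iloc[40:]
        assert la.nunique() == 1 and lb.nunique() == 1
        assert la.iloc[0] != lb.iloc[0]

    def test_identical_patients_deterministic(self):
        m = _dm(np.zeros((8, 3)))
        r1 = ward_cluster(m, k=2)
        r2 = ward_cluster(m, k=2)
        assert (r1.linkage[:, 2] == 0).all()  # merge heights all zero
        assert (r1.labels == r2.labels).all()

    def test_order_invariance_up_to_relabeling(self, rng):
        x = np.vstack([rng.normal(-3, 1, size=(10, 5)), rng.normal(3, 1, size=(12, 5))])
        m1 = _dm(x)
        perm = rng.permutation(len(x))
        m2 = _dm(x[perm], index=[f"p{i}" for i in perm])
        l1 = ward_cluster(m1, k=2).labels
        l2 = ward_cluster(m2, k=2).labels.reindex(l1.index)
        agreement = (l1 == l2).mean()
        assert agreement in (0.0, 1.0)  # equal or fully label-swapped

    def test_too_few_patients_rejected(self):
        with pytest.raises(ConfigError):
            ward_cluster(_dm(np.zeros((3, 4))), k=2)

    def test_opposing_sign_blocks_produce_antisymmetric_heatmap(self, rng):
        """Two patient groups with mirrored up/down feature blocks split
        into two clusters whose column means have opposite sign pattern."""
        up = np.hstack([rng.normal(1, 0.3, size=(30, 6)), rng.normal(-1, 0.3, size=(30, 8))])
        down = np.hstack([rng.normal(-1, 0.3, size=(45, 6)), rng.normal(1, 0.3, size=(45, 8))])
        m = _dm(np.vstack([up, down]))
        res = ward_cluster(m, k=2)
        means = m.data.groupby(res.labels).mean()
        signs = np.sign(means.to_numpy())
        assert (signs[0] == -signs[1]).all()


class TestGroupTtest:
    def test_identical_groups_null_result(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0]]), (2, 1))
        m = _dm(x, normalized=False)
        groups = pd.Series([True] * 3 + [False] * 3, index=m.data.index)
        res = group_ttest(m, groups)
        assert res[0].t == pytest.approx(0.0)
        assert res[0].p == pytest.approx(1.0)

    def test_textbook_welch_values(self):
        # {1,2,3} vs {2,3,4}: t = -sqrt(3/2), df = 4
        m = _dm(np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]]), normalized=False)
        groups = pd.Series([True] * 3 + [False] * 3, index=m.data.index)
        r = group_ttest(m, groups)[0]
        t_hand = -np.sqrt(1.5)
        p_hand = 2 * stats.t.sf(np.sqrt(1.5), df=4)
        assert r.t == pytest.approx(t_hand, abs=1e-12)
        assert r.p == pytest.approx(p_hand, abs=1e-12)
        assert (r.mean_a, r.mean_b) == (2.0, 3.0)

    def test_separated_groups_tiny_p(self, rng):
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])[:, None]
        m = _dm(x, normalized=False)
        groups = pd.Series([True] * 50 + [False] * 50, index=m.data.index)
        assert group_ttest(m, groups)[0].p < 1e-4

    def test_empty_group_rejected(self):
        m = _dm(np.ones((4, 1)), normalized=False)
        with pytest.raises(ValueError, match="non-empty"):
            group_ttest(m, pd.Series([True] * 4, index=m.data.index))


class TestHolm:
    def test_two_pvalue_hand_case(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.3]), [0.3])

    def test_matches_bruteforce_stepdown(self, rng):
        for _ in range(10):
            p = rng.uniform(size=20)
            np.testing.assert_allclose(holm_adjust(p), brute_holm(p), atol=1e-12)

    def test_monotone_and_never_below_raw(self, rng):
        p = rng.uniform(size=25)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestKaplanMeier:
    def test_no_censoring_product_limit_by_hand(self):
        c = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        s_at = dict(zip(c.times, c.survival))
        assert s_at[1.0] == pytest.approx(0.75)
        assert s_at[2.0] == pytest.approx(0.5)
        assert s_at[3.0] == pytest.approx(0.25)
        assert s_at[4.0] == pytest.approx(0.0)
        assert c.median == pytest.approx(2.0)  # first time S <= 0.5

    def test_all_censored_curve_flat_median_undefined(self):
        c = km_estimate([5, 6, 7], [0, 0, 0])
        assert (c.survival == 1.0).all()
        assert not c.median_defined

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(100, 200)
        c = km_estimate(t, np.ones(200))
        for ti, si in zip(c.times[1:], c.survival[1:]):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_censored_sample_matches_bruteforce(self, rng):
        t = rng.exponential(100, 60).round(0)
        e = (rng.random(60) < 0.7).astype(int)
        c = km_estimate(t, e)
        for ti, si in brute_km(t, e):
            idx = np.searchsorted(c.times, ti)
            assert c.survival[idx] == pytest.approx(si, abs=1e-12)

    def test_nonincreasing_starts_at_one(self, rng):
        t = rng.exponential(50, 100)
        e = (rng.random(100) < 0.8).astype(int)
        c = km_estimate(t, e)
        assert c.survival[0] == 1.0 or c.times[0] > 0
        assert (np.diff(c.survival) <= 1e-12).all()

    def test_exponential_median_recovery(self, rng):
        # Exp with median 363 d, ~20% independent censoring, n = 5000
        from deltarad.synthetic import CohortConfig, simulate_survival

        cfg = CohortConfig(pfs_censoring_fraction=0.2)
        draws = [simulate_survival(True, cfg, rng)[:2] for _ in range(5000)]
        c = km_estimate([d[0] for d in draws], [d[1] for d in draws])
        assert c.median == pytest.approx(363, abs=15)


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_small_fixture_matches_hand_tabulation(self):
        ta, ea = [6, 13, 21, 30], [1, 1, 1, 0]
        tb, eb = [10, 15, 24], [1, 0, 1]
        oa, expa, var = brute_logrank(ta, ea, tb, eb)
        stat, p = logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx((oa - expa) ** 2 / var, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf((oa - expa) ** 2 / var, df=1), rel=1e-9)

    def test_symmetric_in_group_labels(self, rng):
        ta = rng.exponential(100, 30)
        tb = rng.exponential(60, 25)
        ea = (rng.random(30) < 0.8).astype(int)
        eb = (rng.random(25) < 0.8).astype(int)
        s1, p1 = logrank_test(ta, ea, tb, eb)
        s2, p2 = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_invariant_under_time_rescaling(self, rng):
        ta = rng.exponential(100, 30)
        tb = rng.exponential(60, 25)
        ea = np.ones(30)
        eb = np.ones(25)
        s1, _ = logrank_test(ta, ea, tb, eb)
        s2, _ = logrank_test(ta * 3.7, ea, tb * 3.7, eb)
        assert s1 == pytest.approx(s2)

    def test_power_at_programmed_medians(self):
        """Exp(median 363) vs Exp(median 180) at n = 64/66 with light
        censoring separates at p < 0.05 in >= 90% of replicates."""
        from deltarad.synthetic import CohortConfig, simulate_survival

        cfg = CohortConfig(pfs_censoring_fraction=0.1)
        hits = 0
        reps = 200
        rng = np.random.default_rng(42)
        for _ in range(reps):
            a = [simulate_survival(True, cfg, rng)[:2] for _ in range(64)]
            b = [simulate_survival(False, cfg, rng)[:2] for _ in range(66)]
            _, p = logrank_test([x[0] for x in a], [x[1] for x in a],
                                [x[0] for x in b], [x[1] for x in b])
            hits += p < 0.05
        assert hits / reps >= 0.90


class TestCohortTable:
    def test_valid_table_roundtrip(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "arm": ["TKI", "PBC"],
                "recist": ["PR", "PD"],
                "pfs_days": [100.0, 50.0],
                "pfs_event": [1, 0],
                "os_days": [200.0, 80.0],
                "os_event": [0, 1],
            }
        )
        t = validate_cohort_table(df)
        assert list(t.index) == ["a", "b"]

    @pytest.mark.parametrize(
        "patch",
        [
            {"patient_id": ["a", "a"]},
            {"arm": ["TKI", "XX"]},
            {"recist": ["PR", "CRX"]},
            {"pfs_event": [1, 2]},
            {"pfs_days": [-1.0, 50.0]},
        ],
    )
    def test_invalid_tables_rejected(self, patch):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "arm": ["TKI", "PBC"],
                "recist": ["PR", "PD"],
                "pfs_days": [100.0, 50.0],
                "pfs_event": [1, 0],
                "os_days": [200.0, 80.0],
                "os_event": [0, 1],
            }
        )
        for k, v in patch.items():
            df[k] = v
        with pytest.raises(SchemaError):
            validate_cohort_table(df)

    def test_grouping_conventions(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "arm": ["TKI"] * 3,
                "recist": ["PR", "SD", "PD"],
                "pfs_days": [365.0, 366.0, 100.0],
                "pfs_event": [1, 1, 1],
                "os_days": [1.0, 1.0, 1.0],
                "os_event": [1, 1, 1],
            }
        )
        t = validate_cohort_table(df)
        g = GroupingConfig()
        assert list(g.pfs_groups(t)) == [False, True, False]  # strictly > 365
        assert list(g.response_groups(t)) == [True, True, False]
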