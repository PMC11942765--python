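"""Correlation suite: PCA logic, clustering, VIP, cone, RF, consensus."""

import numpy as np
import pandas as pd
import pytest

from polytg.correlations import (
    FeatureTable,
    cluster_tg_profile,
    compute_vip,
    consensus,
    correlation_report,
    loading_cone_select,
    pairwise_tg_correlation,
    rf_importance,
    run_pca,
)
from polytg.errors import DataError
from polytg.synthetic import (
    generate_cluster_dataset,
    generate_correlation_dataset,
)


def _table(X, tg=None, ids=None):
    n = len(X)
    return FeatureTable(
        ids=ids or [f"p{i}" for i in range(n)],
        X=pd.DataFrame(X).add_prefix("f"),
        tg=None if tg is None else pd.Series(np.asarray(tg, dtype=float)),
    )


class TestPCA:
    def test_rank_two_data_has_two_variance_fractions(self):
        rng = np.random.default_rng(0)
        latents = rng.normal(size=(40, 2))
        W = rng.normal(size=(2, 8))
        t = _table(latents @ W)
        res = run_pca(t)
        assert np.sum(res.variance_fractions > 1e-9) == 2
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_collinear_tg_adds_no_variance_direction(self):
        # Tg an exact linear function of redundant rank-2 features: the
        # rank (number of independent variance directions) is unchanged and
        # the variance profile moves only at the O(1/p) renormalisation
        # level that adding one column implies.
        rng = np.random.default_rng(1)
        latents = rng.normal(size=(60, 2))
        W = rng.normal(size=(2, 12))
        X = latents @ W
        t = _table(X, tg=X[:, 2] * 3.0 + 10.0)
        without = run_pca(t, include_tg=False).variance_fractions
        with_tg = run_pca(t, include_tg=True).variance_fractions
        assert np.sum(without > 1e-9) == np.sum(with_tg > 1e-9) == 2
        assert np.allclose(without[:2], with_tg[:2], atol=0.05)

    def test_exactly_collinear_single_factor_limit(self):
        # in the fully redundant limit (every feature and Tg driven by one
        # factor) the variance fractions are exactly invariant
        rng = np.random.default_rng(2)
        f = rng.normal(size=40)
        X = np.outer(f, rng.uniform(0.5, 2.0, size=10))
        t = _table(X, tg=2.0 * f + 30.0)
        without = run_pca(t, include_tg=False).variance_fractions
        with_tg = run_pca(t, include_tg=True).variance_fractions
        k = min(len(without), len(with_tg))
        assert np.allclose(without[:k], with_tg[:k], atol=1e-9)

    def test_loading_signs_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        a = run_pca(_table(X)).loadings
        b = run_pca(_table(X)).loadings
        pd.testing.assert_frame_equal(a, b)
        # largest-magnitude entry of every component is positive
        for col in a.columns:
            v = a[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_too_few_rows(self):
        with pytest.raises(DataError):
            run_pca(_table(np.zeros((2, 4)) + np.arange(4)))


class TestClusters:
    def test_three_blob_recovery_within_2C(self):
        ds = generate_cluster_dataset(seed=5)
        res = run_pca(ds.table.standardize())
        profiles = cluster_tg_profile(
            res.scores, ds.table.tg, ds.table.ids, k=3, seed=5
        )
        means = sorted(p.mean_tg for p in profiles)
        for got, want in zip(means, [50.0, 120.0, 200.0]):
            # within 2 C of the generating mean up to sampling error of the
            # cluster-mean itself
            assert got == pytest.approx(want, abs=2.0)

    def test_k1_gives_global_mean(self):
        ds = generate_cluster_dataset(seed=1)
        res = run_pca(ds.table.standardize())
        (p,) = cluster_tg_profile(res.scores, ds.table.tg, ds.table.ids, k=1, seed=1)
        assert p.mean_tg == pytest.approx(float(ds.table.tg.mean()))

    def test_permutation_invariance_up_to_relabelling(self):
        ds = generate_cluster_dataset(seed=3)
        res = run_pca(ds.table.standardize())
        prof = cluster_tg_profile(res.scores, ds.table.tg, ds.table.ids, k=3, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.table.n)
        prof_p = cluster_tg_profile(
            res.scores[perm],
            ds.table.tg.iloc[perm].reset_index(drop=True),
            [ds.table.ids[i] for i in perm],
            k=3,
            seed=3,
        )
        got = [(round(p.mean_tg, 6), sorted(p.member_ids)) for p in prof]
        got_p = [(round(p.mean_tg, 6), sorted(p.member_ids)) for p in prof_p]
        assert got == got_p

    def test_k_exceeding_rows_errors(self):
        ds = generate_cluster_dataset(n_per_cluster=2, seed=0)
        res = run_pca(ds.table.standardize())
        with pytest.raises(DataError):
            cluster_tg_profile(res.scores, ds.table.tg, ds.table.ids, k=100, seed=0)


class TestVIP:
    def _table_with_planted(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        tg = rng.normal(size=n) * 50 + 100
        X = pd.DataFrame(
            {
                "copy_tg": tg + 0.0,
                "neg_tg": -tg,
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
                "noise3": rng.normal(size=n),
            }
        )
        return FeatureTable(
            ids=[str(i) for i in range(n)], X=X, tg=pd.Series(tg)
        )

    def test_copy_of_tg_is_maximal_and_antisymmetric(self):
        vip = compute_vip(self._table_with_planted())
        assert vip.abs().idxmax() in ("copy_tg", "neg_tg")
        assert vip["copy_tg"] > 0 > vip["neg_tg"]
        assert vip["copy_tg"] == pytest.approx(-vip["neg_tg"], abs=1e-9)

    def test_orthogonal_feature_has_tiny_vip(self):
        vip = compute_vip(self._table_with_planted(seed=4))
        for f in ("noise1", "noise2", "noise3"):
            assert abs(vip[f]) < 0.05

    def test_truncation_warning(self):
        t = self._table_with_planted(n=30)
        with pytest.warns(UserWarning, match="truncating"):
            compute_vip(t, n_pcs=50)


class TestCone:
    def test_copy_and_negation_selected_with_signs(self):
        t = TestVIP()._table_with_planted(seed=7)
        res = run_pca(t, include_tg=True)
        members = loading_cone_select(res.loadings, cone_half_angle_deg=30)
        assert members.get("copy_tg") == "+"
        assert members.get("neg_tg") == "-"
        assert "noise1" not in members


class TestRF:
    def test_planted_feature_ranked_first(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 150
            X = pd.DataFrame(rng.normal(size=(n, 8))).add_prefix("f")
            tg = 100 + 40 * X["f3"].to_numpy() + rng.normal(scale=2, size=n)
            t = FeatureTable(
                ids=[str(i) for i in range(n)], X=X, tg=pd.Series(tg)
            )
            imp = rf_importance(t, n_trees=200, seed=seed)
            wins += imp.idxmax() == "f3"
        assert wins >= 19

    def test_no_spurious_dominance_on_pure_noise(self):
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(size=(120, 10))).add_prefix("f")
            t = FeatureTable(
                ids=[str(i) for i in range(120)],
                X=X,
                tg=pd.Series(rng.normal(size=120)),
            )
            imp = rf_importance(t, n_trees=200, seed=seed)
            ok += imp.max() < 3 * imp.mean()
        assert ok >= 4

    def test_duplicated_feature_shares_importance(self):
        rng = np.random.default_rng(0)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 6))).add_prefix("f")
        tg = 50 * X["f0"].to_numpy() + rng.normal(scale=2, size=n)
        single = rf_importance(
            FeatureTable([str(i) for i in range(n)], X, pd.Series(tg)),
            n_trees=200,
            seed=1,
        )
        X2 = X.copy()
        X2["f0_dup"] = X["f0"]
        dup = rf_importance(
            FeatureTable([str(i) for i in range(n)], X2, pd.Series(tg)),
            n_trees=200,
            seed=1,
        )
        assert dup["f0"] + dup["f0_dup"] >= 0.8 * single["f0"]


class TestConsensus:
    def test_planted_anti_tg_gets_four_votes_sign_minus(self):
        ds = generate_correlation_dataset(80, seed=3, planted_anti_tg=True)
        rep = correlation_report(ds.table, rf_trees=200, seed=3)
        planted = ds.ground_truth["planted_anti_tg"]
        row = next(r for r in rep.consensus if r.feature == planted)
        assert row.times_selected == 4
        assert row.correlation_sign == "-"

    def test_conflicting_signs_reported(self):
        pairwise = pd.Series({"a": 0.9, "b": -0.5})
        vip = pd.Series({"a": -0.2, "b": -0.4})
        rows = consensus(pairwise, vip, {}, pd.Series({"a": 0.6, "b": 0.4}), top_n=2)
        sign = {r.feature: r.correlation_sign for r in rows}
        assert sign["a"] == "+ and -"
        assert sign["b"] == "-"

    def test_rf_only_selection_has_no_sign(self):
        pairwise = pd.Series({"a": 0.9, "b": 0.01, "c": 0.8})
        vip = pd.Series({"a": 0.5, "b": 0.001, "c": 0.3})
        rf = pd.Series({"a": 0.1, "b": 0.8, "c": 0.1})
        rows = consensus(pairwise, vip, {}, rf, top_n=1)
        sign = {r.feature: r.correlation_sign for r in rows}
        assert sign["b"] == "n/a"

    def test_null_calibration_pairwise(self):
        # |r| of shuffled Tg stays below 3/sqrt(n) for most features
        ds = generate_correlation_dataset(200, seed=9)
        rng = np.random.default_rng(9)
        shuffled = ds.table.tg.sample(
            frac=1.0, random_state=9
        ).reset_index(drop=True)
        t = FeatureTable(ids=ds.table.ids, X=ds.table.X, tg=shuffled)
        r = pairwise_tg_correlation(t)
        frac_ok = (r.abs() < 3 / np.sqrt(t.n)).mean()
        assert frac_ok >= 0.95
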