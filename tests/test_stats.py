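"""Tests of PCA, separability and the nonparametric group comparisons."""

import numpy as np
import pandas as pd
import pytest

from sleephrv.stats import (
    FeatureMatrix,
    _silhouette,
    build_feature_matrix,
    flag_outliers,
    group_compare,
    pca,
    separability_report,
)


def brute_force_eigs_2x2(S):
    """Characteristic-polynomial eigenvalues of a symmetric 2x2 matrix."""
    tr, det = S[0, 0] + S[1, 1], S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    disc = np.sqrt(tr**2 - 4 * det)
    return np.array([(tr + disc) / 2, (tr - disc) / 2])


class TestPCA:
    def test_single_axis_carries_all_variance(self, rng):
        t = rng.standard_normal(50)
        X = np.outer(t, [1.0, 2.0, -1.0])
        res = pca(X, k=1, scale=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_uncorrelated_unit_columns_identity_covariance(self, rng):
        X = rng.standard_normal((4000, 5))
        res = pca(X, k=5)
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=0.15)

    def test_two_column_correlation_closed_form(self, rng):
        rho = 0.8
        cov = [[1, rho], [rho, 1]]
        X = rng.multivariate_normal([0, 0], cov, size=200000)
        res = pca(X, k=2)
        np.testing.assert_allclose(res.eigenvalues, [1 + rho, 1 - rho], atol=0.02)

    def test_round_trip_reconstruction(self, rng):
        X = rng.standard_normal((30, 6))
        res = pca(X, k=6)
        Xc = (X - res.mean) / res.scale
        np.testing.assert_allclose(
            res.scores @ res.eigenvectors.T, Xc, atol=1e-10
        )

    def test_matches_characteristic_polynomial_on_2x2(self, rng):
        X = rng.standard_normal((100, 2)) @ np.array([[1.0, 0.3], [0.0, 0.7]])
        res = pca(X, k=2, scale=False)
        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc / (X.shape[0] - 1)
        np.testing.assert_allclose(res.eigenvalues, brute_force_eigs_2x2(S), atol=1e-10)

    def test_score_covariance_is_diagonal_eigenvalues(self, rng):
        X = rng.standard_normal((500, 4)) @ rng.standard_normal((4, 4))
        res = pca(X, k=4, scale=False)
        C = res.scores.T @ res.scores / (X.shape[0] - 1)
        np.testing.assert_allclose(C, np.diag(res.eigenvalues), atol=1e-8)

    def test_sign_convention(self, rng):
        X = rng.standard_normal((40, 3))
        res = pca(X)
        for j in range(3):
            v = res.eigenvectors[:, j]
            assert v[np.argmax(np.abs(v))] > 0

    def test_k_beyond_rank_rejected(self, rng):
        t = rng.standard_normal(20)
        X = np.outer(t, [1.0, 2.0, 3.0])  # rank 1
        with pytest.raises(ValueError):
            pca(X, k=2, scale=False)

    def test_agrees_with_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = rng.standard_normal((60, 5)) @ rng.standard_normal((5, 5))
        res = pca(X, k=3, scale=False)
        ref = sklearn.PCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            res.eigenvalues[:3], ref.explained_variance_, atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(res.scores), np.abs(ref.transform(X)), atol=1e-8
        )


class TestSeparability:
    def _clusters(self, rng, sep=10.0, n=10):
        centers = np.array([[0, 0, 0], [sep, 0, 0], [0, sep, 0]], float)
        X = np.vstack([c + rng.standard_normal((n, 3)) for c in centers])
        labels = np.repeat(["a", "b", "c"], n)
        return X, labels

    def test_separated_clusters_perfect_accuracy(self, rng):
        X, labels = self._clusters(rng)
        rep = separability_report(X, labels)
        assert rep["nearest_centroid_accuracy"] == 1.0
        assert rep["silhouette"] > 0.7

    def test_permuted_labels_chance_accuracy(self, rng):
        X, labels = self._clusters(rng)
        accs = [
            separability_report(X, rng.permutation(labels))["nearest_centroid_accuracy"]
            for _ in range(20)
        ]
        assert abs(np.mean(accs) - 1 / 3) < 0.12

    def test_identical_groups_zero_separation(self, rng):
        X = np.tile(rng.standard_normal((12, 3)), (2, 1))
        labels = np.repeat(["a", "b"], 12)
        rep = separability_report(X, labels)
        assert abs(rep["silhouette"]) < 0.15

    def test_degenerate_group_reported_not_fatal(self, rng):
        X = rng.standard_normal((7, 3))
        labels = np.array(["a"] * 5 + ["b"] * 2)
        rep = separability_report(X, labels)
        assert rep["degenerate_groups"] == ["b"]

    def test_silhouette_agrees_with_sklearn(self, rng):
        metrics = pytest.importorskip("sklearn.metrics")
        X, labels = self._clusters(rng, sep=3.0)
        assert _silhouette(X, labels) == pytest.approx(
            metrics.silhouette_score(X, labels), abs=1e-10
        )


class TestGroupCompare:
    def test_identical_groups_p_near_one(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)])
        labels = np.repeat(["a", "b"], 10)
        out = group_compare(x, labels)
        assert out["rank_sum_p"] > 0.9

    def test_large_shift_highly_significant(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 10.0
        out = group_compare(np.concatenate([a, b]), np.repeat(["a", "b"], 10))
        assert out["rank_sum_p"] < 0.001

    def test_scale_only_difference_detected_by_spread_test(self, rng):
        """A pure variance change triggers Brown-Forsythe, not rank-sum."""
        a = rng.standard_normal(60)
        b = 6.0 * rng.standard_normal(60)
        out = group_compare(np.concatenate([a, b]), np.repeat(["a", "b"], 60))
        assert out["brown_forsythe_p"] < 0.01
        assert out["rank_sum_p"] > 0.05

    def test_constant_column_flagged(self):
        out = group_compare(np.ones(20), np.repeat(["a", "b"], 10))
        assert not out["spread_test_defined"]

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            group_compare(np.arange(10.0), np.repeat("a", 10))


class TestOutliers:
    def test_single_distant_point_flagged(self):
        vals = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 8.0])
        flags = flag_outliers(vals)
        assert flags.sum() == 1 and flags[-1]

    def test_at_most_one_per_group(self):
        base = [1.0, 1.05, 0.95, 1.02, 0.98, 1.01, 0.99]
        vals = np.array(base + [50.0, 60.0] + base + [-40.0, -50.0])
        labels = np.repeat(["a", "b"], 9)
        flags = flag_outliers(vals, labels)
        assert flags[labels == "a"].sum() == 1
        assert vals[flags & (labels == "a")][0] == 60.0
        assert flags[labels == "b"].sum() == 1
        assert vals[flags & (labels == "b")][0] == -50.0

    def test_clean_data_unflagged(self, rng):
        assert flag_outliers(np.linspace(0, 1, 20)).sum() == 0


class TestGeneratorSeparability:
    def test_early_vs_non_in_raw_feature_space(self):
        """Early-pregnancy records separate from non-pregnancy on the raw
        {meanRR, rmsRR, meanMM} quarter features."""
        import sleephrv as sh

        rows = []
        for g in ("non", "early"):
            for seed in range(1, 6):
                cfg = sh.config_for_group(g, seed=seed)
                hyp = sh.generate_hypnogram(cfg)
                beats = sh.generate_rr(cfg, hyp)
                df = sh.analyze_quarters(beats, hypnogram=hyp)
                df.insert(0, "group", g)
                df.insert(0, "record_id", f"{g}{seed}")
                rows.append(df)
        tidy = pd.concat(rows, ignore_index=True)
        fm = build_feature_matrix(tidy, features=["meanRR", "rmsRR", "meanMM"])
        X = (fm.X - fm.X.mean(axis=0)) / fm.X.std(axis=0, ddof=1)
        rep = separability_report(X, fm.labels, fm.record_ids)
        assert rep["nearest_centroid_accuracy"] >= 0.8


class TestFeatureMatrix:
    def _tidy(self):
        rows = []
        for rec, grp in [("r1", "non"), ("r2", "non"), ("r3", "early")]:
            for i, q in enumerate(["Q1", "Q2", "Q3", "Q4"]):
                rows.append(
                    {"record_id": rec, "group": grp, "quarter": q,
                     "meanRR": 0.9 + 0.01 * i, "sdRR": 0.05}
                )
        return pd.DataFrame(rows)

    def test_pivot_shape_and_labels(self):
        fm = build_feature_matrix(self._tidy())
        assert fm.X.shape == (3, 8)  # 2 indices x 4 quarters
        assert sorted(set(fm.labels)) == ["early", "non"]
        assert "meanRR_Q1" in fm.feature_names

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            FeatureMatrix(
                X=np.array([[1.0, np.nan]]), labels=np.array(["a"]),
                feature_names=["x", "y"], record_ids=["r"],
            )
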