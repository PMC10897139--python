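"""ANOVA, Pearson matrices, PCA retention and site clustering against
closed-form oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import adjusted_rand_score

from riverwq.stats import (
    anova_by_site,
    cluster_sites,
    correlation_matrix,
    pearson_with_p,
    run_pca,
    significance_tier,
)


def records_df(groups):
    rows = [
        {"site_id": sid, "x": v} for sid, vals in groups.items() for v in vals
    ]
    return pd.DataFrame(rows)


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        res = anova_by_site(records_df({"a": [1, 2, 3], "b": [1, 2, 3]}), "x")
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_sum_of_squares(self):
        # groups {0,0,0,0} vs {1,1,1,2}: SSB=3.125, SSW=0.75, df=(1,6), F=25
        res = anova_by_site(records_df({"a": [0, 0, 0, 0], "b": [1, 1, 1, 2]}), "x")
        assert res.F == pytest.approx(25.0, rel=1e-12)

    def test_two_group_f_equals_pooled_t_squared(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(11)
        for _ in range(20):
            a, b = rng.normal(size=8), rng.normal(1, 2, size=6)
            res = anova_by_site(records_df({"a": a, "b": b}), "x")
            t, p = ttest_ind(a, b)
            assert res.F == pytest.approx(t**2, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_degenerate_and_invalid_inputs(self):
        res = anova_by_site(records_df({"a": [0, 0], "b": [1, 1]}), "x")
        assert res.p == 0.0 and math.isinf(res.F) and "0 limit" in res.note
        with pytest.raises(ValueError, match="site b"):
            anova_by_site(records_df({"a": [1, 2], "b": [3]}), "x")
        with pytest.raises(ValueError, match="two sites"):
            anova_by_site(records_df({"a": [1, 2]}), "x")


class TestPearson:
    def test_textbook_sigma_formula(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        n = 4
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt((n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2))
        r_oracle = num / den
        t = r_oracle * math.sqrt((n - 2) / (1 - r_oracle**2))
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t), n - 2)
        r, p, n_used = pearson_with_p(x, y)
        assert r == pytest.approx(r_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)
        assert n_used == 4

    def test_random_vectors_match_closed_form(self, rng):
        from scipy.stats import t as tdist

        for _ in range(100):
            n = int(rng.integers(4, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p, _ = pearson_with_p(x, y)
            rr = np.corrcoef(x, y)[0, 1]
            t = rr * math.sqrt((n - 2) / (1 - rr**2))
            assert r == pytest.approx(rr, abs=1e-10)
            assert p == pytest.approx(2 * tdist.sf(abs(t), n - 2), abs=1e-10)

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        r_xy, _, _ = pearson_with_p(x, y)
        r_yx, _, _ = pearson_with_p(y, x)
        r_scaled, _, _ = pearson_with_p(3.5 * x + 2, y)
        r_flipped, _, _ = pearson_with_p(-x, y)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        assert r_scaled == pytest.approx(r_xy, abs=1e-12)
        assert r_flipped == pytest.approx(-r_xy, abs=1e-12)

    def test_zero_variance_is_undefined_not_zero(self):
        r, p, n = pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p) and n == 4
        assert significance_tier(p) == "undefined"


def _comp_metrics(n=5):
    comp = pd.DataFrame(
        {
            "site_id": [f"S{i}" for i in range(n)],
            "scale": "local",
            "season": "base",
            "cropland": np.linspace(10, 50, n),
            "forest": np.linspace(50, 10, n),
        }
    )
    metrics = pd.DataFrame(
        {"site_id": [f"S{i}" for i in range(n)], "wqi": 2 * np.linspace(10, 50, n)}
    )
    return comp, metrics


class TestCorrelationMatrix:
    def test_perfect_linear_relations(self):
        comp, metrics = _comp_metrics()
        out = correlation_matrix(comp, metrics, "local", "base").set_index("lulc_class")
        assert out.loc["cropland", "r"] == pytest.approx(1.0)
        assert out.loc["cropland", "tier"] == "p<0.01"
        assert out.loc["forest", "r"] == pytest.approx(-1.0)
        assert (out["n"] == 5).all()

    def test_requires_three_common_sites(self):
        comp, metrics = _comp_metrics(2)
        with pytest.raises(ValueError, match="3 common sites"):
            correlation_matrix(comp, metrics, "local", "base")

    def test_bh_correction_only_raises_p(self):
        comp, metrics = _comp_metrics(6)
        rng = np.random.default_rng(0)
        metrics["noise"] = rng.normal(size=6)
        plain = correlation_matrix(comp, metrics, "local", "base")
        adj = correlation_matrix(comp, metrics, "local", "base", bh_correction=True)
        assert (adj["p"].to_numpy() >= plain["p"].to_numpy() - 1e-15).all()


class TestPCA:
    def test_two_perfectly_correlated_columns(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = run_pca(df)
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-12)
        assert res.pct_variance[0] == pytest.approx(100.0)
        assert res.n_retained == 1

    def test_reconstructs_correlation_matrix(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        res = run_pca(df)
        R = np.corrcoef(df.to_numpy(), rowvar=False)
        recon = res.loadings.to_numpy() @ np.diag(res.eigenvalues) @ res.loadings.to_numpy().T
        assert np.linalg.norm(recon - R) < 1e-8
        assert res.pct_variance.sum() == pytest.approx(100.0)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_retention_matches_direct_eigendecomposition(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 8)))
        df.columns = [f"v{i}" for i in range(8)]
        df["v7"] = df["v0"] * 0.9 + 0.1 * df["v7"]  # induce structure
        res = run_pca(df)
        eig = np.sort(np.linalg.eigvalsh(np.corrcoef(df.to_numpy(), rowvar=False)))[::-1]
        assert res.eigenvalues == pytest.approx(eig, abs=1e-10)
        assert res.n_retained == int((eig >= 1.0).sum())

    def test_matches_sklearn_on_standardized_data(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        res = run_pca(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        sk = SkPCA().fit(Z.to_numpy())
        assert res.eigenvalues == pytest.approx(sk.explained_variance_, abs=1e-8)

    def test_dominant_loading_sign_positive(self, rng):
        res = run_pca(pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd")))
        L = res.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.raises(ValueError, match="b"):
            run_pca(df)


class TestClustering:
    def _two_clouds(self, rng, n=12, sep=50.0):
        a = rng.normal(size=(n, 3))
        b = rng.normal(size=(n, 3)) + sep
        X = np.vstack([a, b])
        df = pd.DataFrame(X, columns=["x", "y", "z"])
        df.insert(0, "site_id", [f"S{i}" for i in range(2 * n)])
        truth = np.array([0] * n + [1] * n)
        return df, truth

    def test_separated_clouds_recovered_exactly(self, rng):
        df, truth = self._two_clouds(rng)
        res = cluster_sites(df, k=2)
        labels = np.array([res.labels[s] for s in df["site_id"]])
        # oracle: brute-force nearest-centroid labeling of the true partition
        X = df.drop(columns="site_id").to_numpy()
        centroids = np.stack([X[truth == g].mean(axis=0) for g in (0, 1)])
        oracle = np.argmin(
            ((X[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1
        )
        assert adjusted_rand_score(labels, oracle) == 1.0

    def test_identical_rows_single_cluster(self):
        df = pd.DataFrame({"site_id": list("abcd"), "x": 1.0, "y": 2.0})
        res = cluster_sites(df, k=1, standardize=False)
        assert set(res.labels.values()) == {1}
        assert np.allclose(res.linkage[:, 2], 0.0)

    def test_k_equals_n(self, rng):
        df, _ = self._two_clouds(rng, n=3)
        res = cluster_sites(df, k=6)
        assert sorted(res.labels.values()) == [1, 2, 3, 4, 5, 6]

    def test_row_permutation_changes_only_labels(self, rng):
        df, _ = self._two_clouds(rng, n=6)
        res1 = cluster_sites(df, k=3)
        perm = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        res2 = cluster_sites(perm, k=3)
        l1 = np.array([res1.labels[s] for s in df["site_id"]])
        l2 = np.array([res2.labels[s] for s in df["site_id"]])
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_invalid_k(self, rng):
        df, _ = self._two_clouds(rng, n=2)
        with pytest.raises(ValueError):
            cluster_sites(df, k=0)
        with pytest.raises(ValueError):
            cluster_sites(df, k=5)
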