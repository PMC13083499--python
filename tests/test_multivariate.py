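"""Source-apportionment statistics: correlation, KMO, Bartlett, PCA, Ward."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA as SkPCA
from sklearn.preprocessing import StandardScaler

from ptesrisk.multivariate import (
    CorrelationPCA,
    WardClusterer,
    bartlett_sphericity,
    gate_for_pca,
    kmo,
    pca,
    pearson_matrix,
    ward_cluster,
)


def random_correlation(rng, p, n=200):
    """Sample correlation matrix of correlated Gaussian data."""
    mixing = rng.normal(size=(p, p))
    data = rng.normal(size=(n, p)) @ mixing
    return np.corrcoef(data, rowvar=False)


def partial_corr_by_regression(data, i, j):
    """Oracle: partial correlation of columns i, j given the rest,
    via least-squares residuals — independent of matrix inversion."""
    rest = [k for k in range(data.shape[1]) if k not in (i, j)]
    Z = np.column_stack([np.ones(len(data)), data[:, rest]])
    ri = data[:, i] - Z @ np.linalg.lstsq(Z, data[:, i], rcond=None)[0]
    rj = data[:, j] - Z @ np.linalg.lstsq(Z, data[:, j], rcond=None)[0]
    return np.corrcoef(ri, rj)[0, 1]


class TestPearson:
    def test_perfect_positive_and_negative(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0]})
        corr = pearson_matrix(df)
        assert corr.loc["x", "y"] == pytest.approx(1.0)
        df["z"] = -df["x"]
        assert pearson_matrix(df).loc["x", "z"] == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 1.0, 4.0, 3.0]})
        assert pearson_matrix(df).loc["x", "y"] == pytest.approx(0.6)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        corr = pearson_matrix(df)
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert (corr.abs() <= 1 + 1e-12).all().all()

    def test_zero_variance_reported_missing_not_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        corr = pearson_matrix(df)
        assert np.isnan(corr.loc["x", "c"])

    def test_too_few_stations_rejected(self):
        with pytest.raises(ValueError, match="3 stations"):
            pearson_matrix(pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0]}))


class TestKmo:
    def test_matches_regression_residual_oracle(self, rng):
        for p in (3, 4, 5):
            mixing = rng.normal(size=(p, p))
            data = rng.normal(size=(300, p)) @ mixing
            R = np.corrcoef(data, rowvar=False)
            r2 = a2 = 0.0
            for i in range(p):
                for j in range(p):
                    if i != j:
                        r2 += R[i, j] ** 2
                        a2 += partial_corr_by_regression(data, i, j) ** 2
            assert kmo(R) == pytest.approx(r2 / (r2 + a2), abs=1e-10)

    def test_equicorrelated_closed_form(self):
        # for equicorrelation r the partials are r/(1+(p-2)r)
        p, r = 4, 0.9
        R = np.full((p, p), r)
        np.fill_diagonal(R, 1.0)
        a = r / (1 + (p - 2) * r)
        expected = r**2 / (r**2 + a**2)
        assert kmo(R) == pytest.approx(expected, abs=1e-10)

    def test_bounded_on_random_pd_matrices(self, rng):
        for _ in range(10):
            R = random_correlation(rng, int(rng.integers(3, 7)))
            assert 0.0 <= kmo(R) <= 1.0

    def test_singular_matrix_advises_ridge(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            kmo(R)
        assert 0.0 <= kmo(R, ridge=1e-8) <= 1.0


class TestBartlett:
    def test_identity_gives_zero_statistic(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), n=30)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 10
        assert p == pytest.approx(1.0)

    def test_hand_formula_two_variables(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        chi2, df, p = bartlett_sphericity(R, n=15)
        assert chi2 == pytest.approx(-(14 - 9 / 6) * np.log(0.75), rel=1e-12)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(chi2, 1), rel=1e-12)

    def test_statistic_nonnegative(self, rng):
        for _ in range(5):
            R = random_correlation(rng, 4)
            chi2, _, _ = bartlett_sphericity(R, n=50)
            assert chi2 >= 0

    def test_requires_more_observations_than_variables(self):
        with pytest.raises(ValueError, match="n > p"):
            bartlett_sphericity(np.eye(5), n=5)


class TestPca:
    def test_two_variable_closed_form(self):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=4000)
        df = pd.DataFrame(z, columns=["a", "b"])
        r = df.corr().loc["a", "b"]
        res = pca(df)
        np.testing.assert_allclose(res.eigenvalues, [1 + r, 1 - r], atol=1e-12)
        assert res.explained_pct[0] == pytest.approx(100 * (1 + r) / 2)

    def test_eigenvalue_sum_and_explained_sum(self, synthetic_pair):
        fish, _ = synthetic_pair
        res = pca(fish)
        assert res.eigenvalues.sum() == pytest.approx(len(fish.elements), abs=1e-8)
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert res.n_retained == int((res.eigenvalues > 1).sum())

    def test_matches_sklearn_eigenvalues(self, synthetic_pair):
        fish, _ = synthetic_pair
        res = pca(fish)
        z = StandardScaler().fit_transform(fish.values)
        # rescale so the ddof=1 covariance equals the correlation matrix
        z *= np.sqrt((len(z) - 1) / len(z))
        sk = SkPCA().fit(z)
        np.testing.assert_allclose(res.eigenvalues, sk.explained_variance_,
                                   atol=1e-8)

    def test_loading_columns_orthogonal_and_sign_fixed(self, synthetic_pair):
        fish, _ = synthetic_pair
        res = pca(fish)
        comp = res.components.to_numpy()
        np.testing.assert_allclose(comp.T @ comp, np.eye(comp.shape[1]),
                                   atol=1e-10)
        for j in range(comp.shape[1]):
            assert comp[np.argmax(np.abs(comp[:, j])), j] > 0

    def test_invariant_to_affine_rescaling(self, synthetic_pair):
        fish, _ = synthetic_pair
        scaled = fish.values * 1000.0 + 5.0
        np.testing.assert_allclose(
            pca(fish).eigenvalues, pca(scaled).eigenvalues, atol=1e-10
        )

    def test_zero_variance_column_dropped_with_notice(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        df["flat"] = 2.0
        with pytest.warns(UserWarning, match="flat"):
            res = pca(df)
        assert "flat" in res.dropped_zero_variance
        assert "flat" not in res.loadings.index

    def test_transform_scores_shape(self, synthetic_pair):
        fish, _ = synthetic_pair
        model = CorrelationPCA(n_components=3).fit(fish)
        scores = model.transform(fish)
        assert scores.shape == (15, 3)


def two_blob_table(rng, n_per=10, sep=8.0):
    """Two well-separated element groups across stations."""
    base1 = rng.normal(0, 1, size=(12, 1))
    base2 = rng.normal(sep, 1, size=(12, 1))
    cols, truth = {}, {}
    for i in range(n_per):
        cols[f"g1_{i}"] = (base1 + rng.normal(0, 0.3, size=(12, 1))).ravel()
        truth[f"g1_{i}"] = 1
        cols[f"g2_{i}"] = (base2 + rng.normal(0, 0.3, size=(12, 1))).ravel()
        truth[f"g2_{i}"] = 2
    return pd.DataFrame(cols), truth


class TestWard:
    def test_two_blobs_recovered_perfectly(self, rng):
        df, truth = two_blob_table(rng)
        res = ward_cluster(df, axis="elements", k=2)
        groups = res.groups()
        assert len(groups) == 2
        recovered = [set(v) for v in groups.values()]
        expected = [
            {k for k, g in truth.items() if g == 1},
            {k for k, g in truth.items() if g == 2},
        ]
        assert recovered == expected or recovered == expected[::-1]

    def test_matches_sklearn_agglomerative(self, rng):
        df, _ = two_blob_table(rng)
        ours = ward_cluster(df, axis="elements", k=2).labels
        z = (df - df.mean()) / df.std(ddof=1)
        sk = AgglomerativeClustering(n_clusters=2, linkage="ward").fit(
            z.T.to_numpy()
        )
        sk_labels = pd.Series(sk.labels_, index=df.columns)
        # same partition up to label permutation
        assert (
            pd.crosstab(ours, sk_labels).to_numpy() > 0
        ).sum() == 2

    def test_k_equals_items_gives_singletons(self, tiny_fish_table):
        res = ward_cluster(tiny_fish_table, axis="stations", k=3)
        assert sorted(res.labels) == [1, 2, 3]

    def test_merge_heights_monotone(self, synthetic_pair):
        fish, _ = synthetic_pair
        res = ward_cluster(fish, axis="elements", k=2)
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_invariant_to_item_ordering(self, synthetic_pair):
        fish, _ = synthetic_pair
        res1 = ward_cluster(fish, axis="elements", k=2)
        permuted = fish.values[list(reversed(fish.elements))]
        res2 = ward_cluster(permuted, axis="elements", k=2)
        g1 = {frozenset(v) for v in res1.groups().values()}
        g2 = {frozenset(v) for v in res2.groups().values()}
        assert g1 == g2

    def test_k_out_of_range_rejected(self, tiny_fish_table):
        with pytest.raises(ValueError, match="outside"):
            WardClusterer(axis="stations", k=9).fit(tiny_fish_table)


class TestGate:
    def test_uncorrelated_data_fails(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        assert not gate_for_pca(df).passed

    def test_collinear_synthetic_table_passes(self, rng):
        latent = rng.normal(size=(200, 2))
        noise = rng.normal(scale=0.3, size=(200, 6))
        df = pd.DataFrame(
            np.column_stack([latent[:, [0]] + noise[:, :3],
                             latent[:, [1]] + noise[:, 3:]]),
            columns=list("abcdef"),
        )
        decision = gate_for_pca(df)
        assert decision.passed
        assert decision.kmo > 0.5
        assert decision.bartlett_p < 0.001

    def test_verdict_stable_under_column_permutation(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        df["e"] = df["a"] + rng.normal(scale=0.2, size=50)
        d1 = gate_for_pca(df)
        d2 = gate_for_pca(df[list(reversed(df.columns))])
        assert d1.passed == d2.passed
        assert d1.kmo == pytest.approx(d2.kmo, abs=1e-12)


def test_statistics_invariant_to_affine_rescaling(synthetic_pair):
    """Correlation, KMO and Bartlett cannot depend on units."""
    fish, _ = synthetic_pair
    df = fish.values
    scaled = df * pd.Series(
        np.linspace(2, 50, len(df.columns)), index=df.columns
    ) + 3.0
    c1, c2 = pearson_matrix(df), pearson_matrix(scaled)
    np.testing.assert_allclose(c1, c2, atol=1e-12)
    assert kmo(c1.to_numpy()) == pytest.approx(kmo(c2.to_numpy()), abs=1e-12)
    assert bartlett_sphericity(c1.to_numpy(), 15)[0] == pytest.approx(
        bartlett_sphericity(c2.to_numpy(), 15)[0], abs=1e-9
    )
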