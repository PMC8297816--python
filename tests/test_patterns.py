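"""Pattern layer: scaled PCA with imputation, correlation clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from ohnofate import patterns
from ohnofate.simulate import DEFAULT_TIMEPOINTS_H, archetype_profile


def random_profiles(rng, n_rows=6, n_cols=8):
    return pd.DataFrame(
        rng.normal(0, 1, size=(n_rows, n_cols)),
        index=[f"g{i}" for i in range(n_rows)],
    )


def archetype_matrix(rng, per_arch=5, noise=0.0):
    rows, labels = [], []
    for arch in ("I", "II", "III"):
        base = archetype_profile(arch, DEFAULT_TIMEPOINTS_H, amplitude=3)
        for i in range(per_arch):
            rows.append(base + rng.normal(0, noise, len(base)))
            labels.append(arch)
    m = pd.DataFrame(rows, index=[f"{l}_{i}" for i, l in enumerate(labels)])
    return m, labels


class TestUnitVarianceScale:
    def test_divides_rows_by_their_sd(self):
        m = pd.DataFrame([[0.0, 2.0, 4.0]], index=["g"])  # SD = 2
        scaled = patterns.unit_variance_scale(m)
        assert np.allclose(scaled.loc["g"], [0.0, 1.0, 2.0])

    def test_unit_sd_rows_unchanged(self, rng):
        m = random_profiles(rng)
        m = m.div(m.std(axis=1, ddof=1), axis=0)
        scaled = patterns.unit_variance_scale(m)
        assert np.allclose(scaled, m)

    def test_all_scaled_rows_have_unit_sd(self, rng):
        scaled = patterns.unit_variance_scale(random_profiles(rng))
        assert np.allclose(scaled.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_zero_sd_row_rejected_with_name(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flatgene", "ok"])
        with pytest.raises(ValueError, match="flatgene"):
            patterns.unit_variance_scale(m)


class TestPcaSvdImpute:
    def test_complete_matrix_matches_eigendecomposition_oracle(self, rng):
        for _ in range(5):
            m = random_profiles(rng, 6, 8)
            res = patterns.pca_svd_impute(m, n_components=2)
            X = m.to_numpy() - m.to_numpy().mean(axis=0)
            eigvals, eigvecs = np.linalg.eigh(X.T @ X)
            order = np.argsort(eigvals)[::-1]
            eigvals = np.maximum(eigvals[order], 0)
            var_pct = 100 * eigvals / eigvals.sum()
            k = res.scores.shape[1]
            assert np.allclose(res.variance_explained, var_pct[:k], atol=1e-8)
            scores_oracle = X @ eigvecs[:, order][:, :k]
            assert np.allclose(
                np.abs(res.scores.to_numpy()), np.abs(scores_oracle), atol=1e-8
            )

    def test_variance_explained_sums_to_hundred(self, rng):
        res = patterns.pca_svd_impute(random_profiles(rng))
        assert res.variance_explained.sum() == pytest.approx(100.0)

    def test_rank_one_matrix_loads_everything_on_pc1(self, rng):
        u = rng.normal(size=6)
        v = rng.normal(size=8)
        m = pd.DataFrame(np.outer(u, v))
        res = patterns.pca_svd_impute(m)
        assert res.variance_explained[0] == pytest.approx(100.0, abs=1e-8)

    def test_components_are_orthogonal(self, rng):
        res = patterns.pca_svd_impute(random_profiles(rng, 8, 6))
        L = res.loadings.to_numpy()
        gram = L.T @ L
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_masked_cell_recovered_on_low_rank_matrix(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=8)
        full = np.outer(u, v)
        m = pd.DataFrame(full.copy())
        true_val = m.iloc[3, 4]
        m.iloc[3, 4] = np.nan
        res = patterns.pca_svd_impute(m, n_components=1)
        assert res.converged
        assert abs(res.imputed.iloc[3, 4] - true_val) < 1e-3

    def test_excessive_missingness_rejected(self):
        m = pd.DataFrame(np.full((4, 4), np.nan))
        m.iloc[0] = 1.0
        with pytest.raises(ValueError):
            patterns.pca_svd_impute(m)


class TestPredictionEllipse:
    def test_isotropic_cloud_matches_chi_square_radius(self):
        r = np.random.default_rng(31)
        pts = r.normal(0, 1, size=(500, 2))
        ell = patterns.prediction_ellipse(pts, level=0.95)
        expected = np.sqrt(stats.chi2.ppf(0.95, 2))  # ~2.448
        assert ell.semi_axes[0] == pytest.approx(expected, rel=0.10)
        assert ell.semi_axes[1] == pytest.approx(expected, rel=0.10)

    def test_coverage_close_to_nominal(self):
        r = np.random.default_rng(13)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        pts = r.multivariate_normal([1, -2], cov, size=2000)
        ell = patterns.prediction_ellipse(pts, level=0.95)
        centered = pts - ell.center
        # Mahalanobis radius relative to the sample covariance
        inv = np.linalg.inv(np.cov(pts, rowvar=False))
        d2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
        inside = np.mean(d2 <= stats.chi2.ppf(0.95, 2))
        assert 0.93 <= inside <= 0.97

    def test_degenerate_cloud_flagged(self):
        pts = np.ones((5, 2))
        ell = patterns.prediction_ellipse(pts)
        assert ell.degenerate and np.allclose(ell.semi_axes, 0.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            patterns.prediction_ellipse(np.ones((2, 2)))


class TestPearsonDistance:
    def test_identical_rows_have_zero_distance(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        d = patterns.pearson_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_anticorrelated_rows_have_distance_two(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["a", "b"])
        assert patterns.pearson_distance(m).loc["a", "b"] == pytest.approx(2.0)

    def test_matches_definition_on_random_rows(self, rng):
        m = random_profiles(rng, 5, 7)
        d = patterns.pearson_distance(m)
        for i in m.index:
            for j in m.index:
                xi, xj = m.loc[i].to_numpy(), m.loc[j].to_numpy()
                r = np.corrcoef(xi, xj)[0, 1]
                assert d.loc[i, j] == pytest.approx(1.0 - r, abs=1e-12)

    def test_distance_axioms(self, rng):
        d = patterns.pearson_distance(random_profiles(rng, 6, 9))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 2)).all().all()


class TestHclustAverage:
    def test_identical_profiles_merge_first_at_height_zero(self, rng):
        m = random_profiles(rng, 4, 6)
        m.loc["g1"] = m.loc["g0"]
        tree = patterns.hclust_average(patterns.pearson_distance(m))
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_four_leaf_merge_heights_match_hand_calculation(self):
        labels = list("ABCD")
        d = pd.DataFrame(
            [
                [0.0, 0.2, 0.8, 0.9],
                [0.2, 0.0, 0.7, 0.85],
                [0.8, 0.7, 0.0, 0.3],
                [0.9, 0.85, 0.3, 0.0],
            ],
            index=labels,
            columns=labels,
        )
        tree = patterns.hclust_average(d)
        heights = sorted(tree.linkage[:, 2])
        # UPGMA by hand: (A,B) at 0.2; (C,D) at 0.3;
        # then mean(0.8, 0.9, 0.7, 0.85) = 0.8125
        assert heights == pytest.approx([0.2, 0.3, 0.8125])

    def test_archetype_membership_recovered_at_three_clusters(self, rng):
        m, labels = archetype_matrix(rng, per_arch=5, noise=0.05)
        tree = patterns.hclust_average(patterns.pearson_distance(m))
        flat = patterns.cut_tree(tree, 3)
        assert adjusted_rand_score(labels, [flat[g] for g in m.index]) == 1.0

    def test_missing_distances_rejected(self):
        d = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            patterns.hclust_average(d)

    def test_newick_serialization_contains_all_leaves(self, rng):
        m = random_profiles(rng, 5, 6)
        tree = patterns.hclust_average(patterns.pearson_distance(m))
        nwk = patterns.to_newick(tree)
        assert nwk.endswith(";")
        for leaf in m.index:
            assert leaf in nwk


class TestKmeansProfiles:
    def test_single_cluster_contains_everything(self, rng):
        m = random_profiles(rng, 5, 6)
        res = patterns.kmeans_profiles(m, k=1, seed=0)
        assert set(res.assignments.values()) == {1}

    def test_same_seed_reproduces_assignments(self, rng):
        m, _ = archetype_matrix(rng, per_arch=4, noise=0.3)
        r1 = patterns.kmeans_profiles(m, 3, seed=7)
        r2 = patterns.kmeans_profiles(m, 3, seed=7)
        assert r1.assignments == r2.assignments

    def test_zero_noise_archetypes_partition_exactly(self, rng):
        m, labels = archetype_matrix(rng, per_arch=4, noise=0.0)
        res = patterns.kmeans_profiles(m, 3, seed=1)
        assert adjusted_rand_score(labels, [res.assignments[g] for g in m.index]) == 1.0

    def test_agrees_with_hierarchical_on_clean_archetypes(self, rng):
        m, _ = archetype_matrix(rng, per_arch=5, noise=0.05)
        km = patterns.kmeans_profiles(m, 3, seed=2)
        tree = patterns.hclust_average(patterns.pearson_distance(m))
        flat = patterns.cut_tree(tree, 3)
        ari = adjusted_rand_score(
            [flat[g] for g in m.index], [km.assignments[g] for g in m.index]
        )
        assert ari >= 0.9

    def test_k_larger_than_gene_count_rejected(self, rng):
        with pytest.raises(ValueError):
            patterns.kmeans_profiles(random_profiles(rng, 3, 5), k=4, seed=0)
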