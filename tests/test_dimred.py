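"""CCA similarity, 3-component PCA, ellipsoids and centroid metrics."""

import numpy as np
import pytest
from scipy import linalg, stats

from shearsig.datatypes import ValidationError
from shearsig.dimred import (
    EllipsoidSummary,
    cca_similarity,
    centroid_metrics,
    dispersion_table,
    pca3,
)
from shearsig.preprocess import log2cpm


def svd_cca_oracle(X, Y, n_components):
    """Canonical correlations as singular values of the whitened
    cross-covariance Sxx^-1/2 Sxy Syy^-1/2 (independent route)."""
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    n = X.shape[0]
    Sxx, Syy, Sxy = X.T @ X / (n - 1), Y.T @ Y / (n - 1), X.T @ Y / (n - 1)
    Wx = linalg.fractional_matrix_power(Sxx, -0.5)
    Wy = linalg.fractional_matrix_power(Syy, -0.5)
    return linalg.svd(Wx @ Sxy @ Wy, compute_uv=False)[:n_components]


class TestCca:
    def test_identical_matrices_similarity_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 4))
        sim = cca_similarity(X, X)
        np.testing.assert_allclose(sim.canonical_correlations, 1.0, atol=1e-9)
        assert sim.similarity == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_column_permutation_and_sign(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 4))
        Y = X[:, [2, 0, 3, 1]] * np.array([1.0, -1.0, 1.0, -1.0])
        sim = cca_similarity(X, Y)
        assert sim.similarity == pytest.approx(1.0, abs=1e-9)

    def test_matches_svd_oracle_on_random_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5000, 4))
        Y = rng.normal(size=(5000, 4))
        sim = cca_similarity(X, Y)
        oracle = svd_cca_oracle(X, Y, 3)
        np.testing.assert_allclose(sim.canonical_correlations, oracle, atol=1e-8)
        assert sim.similarity < 1.0

    def test_matches_sklearn_cross_check(self):
        from sklearn.cross_decomposition import CCA as SkCCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 4))
        Y = 0.5 * X[:, :4] + rng.normal(size=(2000, 4))
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        fit = SkCCA(n_components=3, max_iter=5000, tol=1e-10).fit(Xs, Ys)
        U, V = fit.transform(Xs, Ys)
        sk = sorted(
            (abs(float(np.corrcoef(U[:, i], V[:, i])[0, 1])) for i in range(3)),
            reverse=True,
        )
        sim = cca_similarity(X, Y)
        np.testing.assert_allclose(sim.canonical_correlations, sk, atol=1e-5)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(800, 4))
        Y = rng.normal(size=(800, 4))
        a = cca_similarity(X, Y).canonical_correlations
        b = cca_similarity(Y, X).canonical_correlations
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_correlations_sorted_in_unit_interval(self):
        rng = np.random.default_rng(5)
        sim = cca_similarity(rng.normal(size=(300, 4)), rng.normal(size=(300, 4)))
        cc = np.array(sim.canonical_correlations)
        assert np.all(np.diff(cc) <= 1e-12)
        assert np.all((cc >= 0) & (cc <= 1))

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValidationError, match="samples"):
            cca_similarity(rng.normal(size=(100, 2)), rng.normal(size=(100, 4)))


class TestPca3:
    def test_duplicated_samples_have_zero_dispersion(self, four_donor_annotation):
        ann = four_donor_annotation
        rng = np.random.default_rng(0)
        base = rng.normal(8, 2, (50, 24))
        # make all PAH HSS samples identical
        cols = [ann.sample_ids.index(s)
                for s in ann.samples_where(group="PAH", condition="HSS")]
        base[:, cols] = base[:, [cols[0]]]
        from shearsig.datatypes import ExpressionMatrix

        E = ExpressionMatrix([f"g{i}" for i in range(50)], ann.sample_ids,
                             base, "log2cpm")
        _, summaries, _ = pca3(E, ann)
        d = {s.label: s.dispersion for s in summaries}
        assert d["PAH_HSS"] == pytest.approx(0.0, abs=1e-9)
        assert d["control_HSS"] > 1e-3

    def test_explained_variance_ordered(self, small_sim):
        _, cm, ann, _ = small_sim
        _, _, evr = pca3(log2cpm(cm), ann)
        assert evr[0] >= evr[1] >= evr[2]

    def test_scores_invariant_to_gene_order(self, small_sim):
        _, cm, ann, _ = small_sim
        E = log2cpm(cm)
        rng = np.random.default_rng(1)
        perm = rng.permutation(E.n_genes)
        E2 = E.subset_genes([E.gene_ids[i] for i in perm])
        s1, _, _ = pca3(E, ann)
        s2, _, _ = pca3(E2, ann)
        np.testing.assert_allclose(np.abs(s1.to_numpy()), np.abs(s2.to_numpy()),
                                   atol=1e-6)

    def test_isotropic_gaussian_coverage(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(200, 3))
        summ = EllipsoidSummary(
            "g_c", "g", "c", 200, pts.mean(0),
            np.cov(pts, rowvar=False, ddof=1),
            float(stats.chi2.ppf(0.95, 3)),
            float(np.sqrt((np.linalg.norm(pts - pts.mean(0), axis=1) ** 2).mean())),
        )
        cover = summ.contains(pts).mean()
        assert 0.90 <= cover <= 0.99

    def test_singleton_group_flagged_degenerate(self, small_sim):
        import pandas as pd

        from shearsig.datatypes import ExpressionMatrix, SampleAnnotation

        rng = np.random.default_rng(2)
        rows = [
            {"sample_id": f"CTR{i:02d}_Static", "donor_id": f"CTR{i:02d}",
             "group": "control", "condition": "Static"} for i in range(1, 5)
        ] + [{"sample_id": "PAH01_HSS", "donor_id": "PAH01",
              "group": "PAH", "condition": "HSS"}]
        ann = SampleAnnotation(pd.DataFrame(rows))
        E = ExpressionMatrix([f"g{i}" for i in range(30)],
                             [r["sample_id"] for r in rows],
                             rng.normal(size=(30, 5)), "log2cpm")
        _, summaries, _ = pca3(E, ann)
        by_label = {s.label: s for s in summaries}
        assert by_label["PAH_HSS"].degenerate
        np.testing.assert_array_equal(by_label["PAH_HSS"].covariance, 0.0)


class TestCentroidMetrics:
    def _summary(self, label, centroid):
        return EllipsoidSummary(label, "g", "c", 4, np.asarray(centroid, float),
                                np.eye(3), 7.81, 1.0)

    def test_pythagorean_distance(self):
        tab = centroid_metrics([self._summary("a", [0, 0, 0]),
                                self._summary("b", [3, 4, 0])])
        assert tab.loc["a", "b"] == pytest.approx(5.0)
        assert tab.loc["a", "a"] == 0.0

    def test_identical_centroids_distance_zero(self):
        tab = centroid_metrics([self._summary("a", [1, 2, 3]),
                                self._summary("b", [1, 2, 3])])
        assert tab.loc["a", "b"] == 0.0

    def test_invariant_under_common_rotation(self):
        rng = np.random.default_rng(7)
        pts = [rng.normal(size=3) for _ in range(5)]
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        before = centroid_metrics([self._summary(f"s{i}", p)
                                   for i, p in enumerate(pts)])
        after = centroid_metrics([self._summary(f"s{i}", Q @ p)
                                  for i, p in enumerate(pts)])
        np.testing.assert_allclose(before.to_numpy(), after.to_numpy(), atol=1e-9)

    def test_dispersion_table_columns(self, small_sim):
        _, cm, ann, _ = small_sim
        _, summaries, _ = pca3(log2cpm(cm), ann)
        tab = dispersion_table(summaries)
        assert {"group", "condition", "dispersion"} <= set(tab.columns)
        assert len(tab) == 6  # 2 groups x 3 conditions
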