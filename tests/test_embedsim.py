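"""Embedding, similarity-matrix and block-contrast contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from sleepprint.embedsim import (
    EmbeddingConfig,
    SimilarityMatrix,
    block_contrast,
    embed,
    similarity_matrix,
)


def table_from(X, subjects, nights=None, groups=None):
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    frame.insert(0, "subject", subjects)
    frame.insert(1, "night", nights if nights is not None else 1)
    frame.insert(2, "stage", "NREM")
    frame.insert(3, "isi_group", groups if groups is not None else "GSC")
    return frame


class TestEmbed:
    def test_pca_preserves_distances_of_planar_data(self, rng):
        # points in a 2-D linear subspace of R^10: PCA projection is a
        # rigid motion, so all pairwise distances survive exactly
        basis = np.linalg.qr(rng.standard_normal((10, 2)))[0]
        coords2 = rng.standard_normal((40, 2)) * [5, 2]
        X = coords2 @ basis.T
        emb = embed(X, EmbeddingConfig(method="pca"))
        orig = pdist(X)
        new = pdist(emb)
        assert np.max(np.abs(new - orig) / orig) < 1e-9

    def test_pca_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((30, 6))
        emb = embed(X, EmbeddingConfig(method="pca"))
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        proj = Xc @ evecs[:, ::-1][:, :2]
        # same up to per-axis sign
        for j in range(2):
            assert (np.allclose(emb[:, j], proj[:, j], atol=1e-8)
                    or np.allclose(emb[:, j], -proj[:, j], atol=1e-8))

    def test_duplicated_rows_embed_together(self, rng):
        X = np.repeat(rng.standard_normal((15, 5)), 2, axis=0)
        emb = embed(X, EmbeddingConfig(method="pca"))
        assert np.allclose(emb[::2], emb[1::2], atol=1e-6)
        tsne = embed(X, EmbeddingConfig(method="tsne", perplexity=8.0,
                                        max_iter=1000, seed=0))
        diameter = pdist(tsne).max()
        pair_dist = np.linalg.norm(tsne[::2] - tsne[1::2], axis=1)
        assert np.all(pair_dist <= 1e-2 * diameter)

    def test_tsne_separates_well_separated_clusters(self, rng):
        from sklearn.metrics import silhouette_score

        centers = np.zeros((3, 10))
        centers[0, 0], centers[1, 1], centers[2, 2] = 50, 50, 50
        labels = np.repeat([0, 1, 2], 100)
        X = centers[labels] + rng.standard_normal((300, 10))
        emb = embed(X, EmbeddingConfig(method="tsne", seed=1))
        assert silhouette_score(emb, labels) > 0.8

    def test_determinism_given_seed(self, rng):
        X = rng.standard_normal((50, 4))
        cfg = EmbeddingConfig(method="tsne", perplexity=10, max_iter=260,
                              seed=7)
        assert np.array_equal(embed(X, cfg), embed(X, cfg))

    def test_perplexity_bound_enforced(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="perplexity"):
            embed(X, EmbeddingConfig(method="tsne", perplexity=30.0))


class TestSimilarityMatrix:
    def test_identical_rows_have_similarity_one(self, rng):
        X = np.vstack([np.ones((2, 4)), rng.standard_normal((4, 4)) * 5])
        table = table_from(X, ["A", "A", "A", "A", "B", "B"])
        sm = similarity_matrix(table, fraction=1.0,
                               rng=np.random.default_rng(0))
        i, j = 0, 1  # the two identical rows sort first (subject A)
        assert sm.values[i, j] == pytest.approx(1.0)
        assert np.allclose(np.diag(sm.values), 1.0)

    def test_collinear_rows_normalize_linearly(self):
        # equally spaced collinear rows: min-max maps distance d to
        # similarity 1 - d / d_max exactly
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        table = table_from(X, ["A", "A", "B", "B"])
        sm = similarity_matrix(table, fraction=1.0,
                               rng=np.random.default_rng(0))
        for i in range(4):
            for j in range(4):
                assert sm.values[i, j] == pytest.approx(1 - abs(i - j) / 3.0)

    def test_matches_bruteforce_double_loop(self, rng):
        X = rng.standard_normal((12, 6))
        table = table_from(X, [f"S{i % 3}" for i in range(12)])
        sm = similarity_matrix(table, fraction=1.0,
                               rng=np.random.default_rng(1))
        # reconstruct with an explicit O(n^2) loop on the selected rows
        order = np.argsort([f"S{i % 3}" for i in range(12)], kind="stable")
        Xs = X[order]
        n = len(Xs)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = np.sqrt(((Xs[i] - Xs[j]) ** 2).sum())
        expected = 1 - (d - d.min()) / (d.max() - d.min())
        assert np.allclose(sm.values, expected, atol=1e-9)

    def test_rotation_invariance(self, rng):
        X = rng.standard_normal((10, 5))
        Q = np.linalg.qr(rng.standard_normal((5, 5)))[0]
        t1 = table_from(X, [f"S{i % 2}" for i in range(10)])
        t2 = table_from(X @ Q, [f"S{i % 2}" for i in range(10)])
        a = similarity_matrix(t1, 1.0, np.random.default_rng(2))
        b = similarity_matrix(t2, 1.0, np.random.default_rng(2))
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_minmax_endpoints(self, rng):
        X = rng.standard_normal((8, 3))
        table = table_from(X, [f"S{i % 2}" for i in range(8)])
        sm = similarity_matrix(table, 1.0, np.random.default_rng(3))
        assert sm.values.min() == pytest.approx(0.0)
        assert sm.values.max() == pytest.approx(1.0)

    def test_half_fraction_selects_half_per_subject(self, rng):
        X = rng.standard_normal((40, 4))
        table = table_from(X, ["A"] * 20 + ["B"] * 20)
        sm = similarity_matrix(table, 0.5, np.random.default_rng(4))
        assert (sm.subject == "A").sum() == 10
        assert (sm.subject == "B").sum() == 10
        assert set(sm.half) == {0, 1}

    def test_subject_with_too_few_epochs_dropped(self, rng):
        X = rng.standard_normal((22, 4))
        table = table_from(X, ["A"] * 10 + ["B"] * 10 + ["C"] * 2)
        with pytest.warns(UserWarning, match="fewer than 2"):
            sm = similarity_matrix(table, 0.5, np.random.default_rng(5))
        assert "C" not in set(sm.subject)


class TestBlockContrast:
    def _constructed(self, hi=0.9, lo=0.1):
        subjects = np.repeat(["A", "B", "C", "D"], 5)
        groups = np.repeat(["GSC", "GSC", "MSI", "MSI"], 5)
        same = subjects[:, None] == subjects[None, :]
        values = np.where(same, hi, lo)
        np.fill_diagonal(values, 1.0)
        return SimilarityMatrix(values, subjects, np.ones(20, int), groups,
                                np.zeros(20, int))

    def test_constructed_blocks_give_contrast_and_tiny_p(self):
        sm = self._constructed()
        bc = block_contrast(sm, n_permutations=1000,
                            rng=np.random.default_rng(0))
        assert bc.subject_contrast == pytest.approx(0.8)
        assert bc.subject_p <= 0.001

    def test_random_labels_give_null_contrast(self, rng):
        n = 40
        values = squareform(1 / (1 + pdist(rng.standard_normal((n, 3)))))
        np.fill_diagonal(values, 1.0)
        subjects = rng.permutation(np.repeat(["A", "B", "C", "D"], 10))
        groups = np.where(np.isin(subjects, ["A", "B"]), "GSC", "MSI")
        sm = SimilarityMatrix(values, subjects, np.ones(n, int), groups,
                              np.zeros(n, int))
        bc = block_contrast(sm, n_permutations=500,
                            rng=np.random.default_rng(1))
        assert abs(bc.subject_contrast) < 0.1
        assert bc.subject_p > 0.01

    def test_fingerprint_cohort_subject_contrast_but_no_group_contrast(
            self, small_table):
        sm = similarity_matrix(small_table, 0.5, np.random.default_rng(6),
                               stage="NREM")
        bc = block_contrast(sm, n_permutations=500,
                            rng=np.random.default_rng(7))
        assert bc.subject_contrast > 0
        assert bc.subject_p <= 0.01
        assert bc.group_p > 0.01
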