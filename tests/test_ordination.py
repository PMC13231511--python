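"""PCA, PCoA, Ward agglomeration and the gap statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from fightdyn import (
    GapProfile,
    choose_k,
    gap_statistic,
    pca,
    pcoa,
    ward_cluster,
    ward_linkage,
)
from fightdyn.errors import ParameterError, SizeError


def naive_ward(D):
    """Dictionary-based Lance-Williams recursion (un-squared convention)."""
    n = D.shape[0]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {(a, b): D[a, b] for a in range(n) for b in range(a + 1, n)}
    merges = []
    nxt = n
    for _ in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = sorted((active[ai], active[bi]))
                cand = (dist[(a, b)], a, b)
                if best is None or cand < best:
                    best = cand
        d_ij, i, j = best
        ni, nj = sizes[i], sizes[j]
        merges.append((i, j, d_ij))
        active = [c for c in active if c not in (i, j)]
        for k in active:
            nk = sizes[k]
            dki = dist[tuple(sorted((i, k)))]
            dkj = dist[tuple(sorted((j, k)))]
            dist[(k, nxt) if k < nxt else (nxt, k)] = (
                (ni + nk) * dki + (nj + nk) * dkj - nk * d_ij
            ) / (ni + nj + nk)
        sizes[nxt] = ni + nj
        active.append(nxt)
        nxt += 1
    return merges


class TestPca:
    def _frame(self, X):
        return pd.DataFrame(X, index=[f"f{i}" for i in range(X.shape[0])],
                            columns=[f"m{j}" for j in range(X.shape[1])])

    def test_rank_one_data(self):
        t = np.linspace(-1, 1, 8)
        X = np.column_stack([t, 2 * t, -t])
        res = pca(self._frame(X))
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_scores_covariance_diagonal(self):
        rng = np.random.default_rng(0)
        res = pca(self._frame(rng.standard_normal((14, 7))))
        cov = np.cov(res.all_scores, rowvar=False)
        np.testing.assert_allclose(cov, np.diag(res.eigenvalues), atol=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((14, 7))
        res = pca(self._frame(X))
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(res.all_scores @ res.loadings.T, Xc, atol=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        res = pca(self._frame(rng.standard_normal((10, 4))))
        for j in range(res.loadings.shape[1]):
            col = res.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_too_few_rows(self):
        with pytest.raises(SizeError):
            pca(self._frame(np.zeros((2, 3))))

    def test_summary_metrics_are_low_rank(self, default_dataset):
        # duration drives effort and bursts, and the decline profile couples
        # the phase metrics, so three dimensions carry most of the variance
        from fightdyn.metrics import metrics_matrix

        dataset, _ = default_dataset
        res = pca(metrics_matrix(dataset))
        assert res.cumulative_variance_dim1_3 > 0.8


class TestPcoa:
    def test_collinear_three_points(self):
        d = 2.4
        D = np.array([[0, d / 2, d], [d / 2, 0, d / 2], [d, d / 2, 0]], dtype=float)
        res = pcoa(D)
        emb = squareform(pdist(res.all_scores))
        np.testing.assert_allclose(emb, D, atol=1e-10)
        assert res.all_scores.shape[1] == 1  # collinear: a single positive axis

    def test_equilateral_triangle_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(D)
        np.testing.assert_allclose(res.eigenvalues, [0.5, 0.5], atol=1e-12)

    def test_euclidean_embeddable_distances_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((10, 4))
        D = squareform(pdist(pts))
        res = pcoa(D)
        np.testing.assert_allclose(squareform(pdist(res.all_scores)), D, atol=1e-8)
        assert np.all(res.eigenvalues >= -1e-9)

    def test_matches_independent_classical_scaling(self):
        # cross-check against scikit-bio's PCoA on the same matrix
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((8, 3))
        D = squareform(pdist(pts))
        ours = pcoa(D)
        theirs = skbio_pcoa(D, number_of_dimensions=3)
        np.testing.assert_allclose(
            ours.eigenvalues[:3], theirs.eigvals.to_numpy()[:3], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.scores), np.abs(theirs.samples.to_numpy()[:, :3]), atol=1e-6
        )

    def test_variance_fractions_use_positive_part(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((9, 5))
        D = squareform(pdist(pts)) ** 1.5  # non-Euclidean transform
        res = pcoa(D)
        assert res.variance_explained.sum() <= 1.0 + 1e-12
        assert np.all(res.variance_explained >= 0)


class TestWard:
    def test_separated_pairs_merge_first(self):
        D = squareform(pdist(np.array([[0.0], [1.0], [5.0], [6.0]])))
        merges = ward_linkage(D)
        assert {tuple(sorted(m[:2])) for m in merges[:2]} == {(0, 1), (2, 3)}
        assert merges[2][:2] == (4, 5)

    def test_k_equals_n(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((5, 2))
        res = ward_cluster(pts, k=5)
        assert len(set(res.labels_at_k)) == 5

    def test_matches_naive_recursion_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pts = rng.standard_normal((8, 3))
            D = squareform(pdist(pts))
            ours = ward_linkage(D)
            theirs = naive_ward(D)
            assert [m[:2] for m in ours] == [m[:2] for m in theirs]
            np.testing.assert_allclose(
                [m[2] for m in ours], [m[2] for m in theirs], rtol=1e-12
            )

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(8)
        D = squareform(pdist(rng.standard_normal((12, 3))))
        h = [m[2] for m in ward_linkage(D)]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(h, h[1:]))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        pts = np.vstack(
            [c + 0.1 * rng.standard_normal((5, 2)) for c in ([0, 0], [3, 0], [0, 3])]
        )
        labels = ward_cluster(pts, 3).labels_at_k
        perm = rng.permutation(len(pts))
        labels_p = ward_cluster(pts[perm], 3).labels_at_k
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)

    def test_k_out_of_range(self):
        with pytest.raises(ParameterError):
            ward_cluster(np.zeros((4, 2)), k=5)


class TestGap:
    def test_kmax_one_trivial(self):
        rng = np.random.default_rng(10)
        prof = gap_statistic(rng.standard_normal((6, 2)), k_max=1, B=10, seed=0)
        assert prof.chosen_k == 1

    def test_seed_reproducible(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((12, 3))
        a = gap_statistic(X, k_max=4, B=20, seed=5)
        b = gap_statistic(X, k_max=4, B=20, seed=5)
        np.testing.assert_array_equal(a.gap, b.gap)
        np.testing.assert_array_equal(a.se, b.se)

    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(12)
        X = np.vstack(
            [c + 0.05 * rng.standard_normal((20, 2)) for c in ([0, 0], [1, 0], [0, 1])]
        )
        prof = gap_statistic(X, k_max=6, B=50, seed=1)
        assert prof.chosen_k == 3

    def test_se_positive(self):
        rng = np.random.default_rng(13)
        prof = gap_statistic(rng.standard_normal((10, 2)), k_max=4, B=20, seed=2)
        assert np.all(prof.se > 0)


class TestChooseK:
    def test_rule_at_first_k(self):
        prof = GapProfile(np.array([1, 2]), np.zeros(2), np.array([0.5, 0.2]), np.array([0.1, 0.1]))
        assert choose_k(prof) == 1

    def test_rule_arithmetic(self):
        prof = GapProfile(
            np.array([1, 2, 3]), np.zeros(3), np.array([0.1, 0.5, 0.45]),
            np.array([0.05, 0.05, 0.05]),
        )
        assert choose_k(prof) == 2

    def test_argmax_fallback(self):
        prof = GapProfile(
            np.array([1, 2, 3]), np.zeros(3), np.array([0.1, 0.2, 0.3]),
            np.array([1e-6, 1e-6, 1e-6]),
        )
        assert choose_k(prof) == 3
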