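"""Locally-scaled spectral clustering: stage-by-stage oracles and pipeline."""

import numpy as np
import pytest

from conftest import rand_index
from polyclust.analytic_models import (AnalyticModelParams,
                                       linear_dissimilarity)
from polyclust.containers import InvalidParameterError
from polyclust.spectral_clustering import (DegenerateGraphError, ScalingVector,
                                           affinity_matrix, kmeans,
                                           local_scaling, normalized_laplacian,
                                           sorted_rows, spectral_cluster,
                                           spectral_embedding)


def random_symmetric(rng, n, scale=1.0):
    M = rng.uniform(0.1, scale, size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return M


class TestSortedRows:
    def test_simple_row(self):
        X = np.array([[0, 3, 1, 2], [3, 0, 2, 1], [1, 2, 0, 3], [2, 1, 3, 0]],
                     float)
        S = sorted_rows(X)
        assert np.array_equal(S[0], [0, 1, 2, 3])
        assert np.all(S[:, 0] == 0)

    def test_linear_model_row_already_sorted(self):
        X = linear_dissimilarity(AnalyticModelParams(n=5))
        assert np.array_equal(sorted_rows(X)[0], X[0])


class TestLocalScaling:
    def test_hand_computed_example(self):
        # collinear points at 0, 1, 3, 6
        pts = np.array([0.0, 1.0, 3.0, 6.0])
        X = np.abs(pts[:, None] - pts[None, :])
        sigma = local_scaling(sorted_rows(X), q=2).sigma
        assert sigma[0] == pytest.approx((1 + 3) / 2)
        assert sigma[1] == pytest.approx((1 + 2) / 2)

    def test_q_one_reduces_to_nearest_neighbor(self):
        rng = np.random.default_rng(0)
        X = random_symmetric(rng, 8)
        S = sorted_rows(X)
        sigma = local_scaling(S, q=1).sigma
        assert np.allclose(sigma, S[:, 1])

    def test_duplicates_floored_positive(self):
        X = np.zeros((5, 5))
        sigma = local_scaling(sorted_rows(X), q=2).sigma
        assert np.all(sigma > 0)

    def test_q_bounds(self):
        X = random_symmetric(np.random.default_rng(1), 5)
        with pytest.raises(InvalidParameterError):
            local_scaling(sorted_rows(X), q=5)
        with pytest.raises(InvalidParameterError):
            local_scaling(sorted_rows(X), q=0)


class TestAffinity:
    def test_closed_form_values(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0]])
        A = affinity_matrix(X, ScalingVector(sigma=np.ones(2), q=1))
        assert A[0, 1] == 1.0  # zero distance
        assert A[0, 0] == 0.0  # diagonal forced to zero
        sigma = np.array([2.0, 3.0])
        X = np.full((2, 2), np.sqrt(2 * sigma[0] * sigma[1]))
        np.fill_diagonal(X, 0)
        A = affinity_matrix(X, ScalingVector(sigma=sigma, q=1))
        assert A[0, 1] == pytest.approx(np.exp(-1))

    def test_rejects_nonpositive_sigma(self):
        X = np.zeros((2, 2))
        with pytest.raises(InvalidParameterError):
            affinity_matrix(X, ScalingVector(sigma=np.array([1.0, 0.0]), q=1))


class TestLaplacian:
    def test_two_point_graph(self):
        for a in (0.5, 1.0, 7.0):
            A = np.array([[0.0, a], [a, 0.0]])
            L = normalized_laplacian(A)
            assert np.allclose(L, [[0, 1], [1, 0]])

    def test_stationary_eigenvector_identity(self):
        rng = np.random.default_rng(2)
        A = np.exp(-random_symmetric(rng, 12))
        np.fill_diagonal(A, 0)
        L = normalized_laplacian(A)
        v = np.sqrt(A.sum(axis=1))
        assert np.abs(L @ v - v).max() < 1e-9  # eigenvalue exactly 1

    def test_disconnected_blocks_have_multiplicity_two(self):
        rng = np.random.default_rng(3)
        A = np.zeros((8, 8))
        A[:4, :4] = np.exp(-random_symmetric(rng, 4))
        A[4:, 4:] = np.exp(-random_symmetric(rng, 4))
        np.fill_diagonal(A, 0)
        vals = np.linalg.eigvalsh(normalized_laplacian(A))
        assert np.sum(np.abs(vals - 1.0) < 1e-9) == 2

    def test_isolated_point_raises_with_frame(self):
        A = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(DegenerateGraphError, match="frame 3"):
            normalized_laplacian(A)


class TestEmbedding:
    def test_rows_unit_length_and_eigenvalues_sorted(self):
        rng = np.random.default_rng(4)
        A = np.exp(-random_symmetric(rng, 15))
        np.fill_diagonal(A, 0)
        emb = spectral_embedding(normalized_laplacian(A), k=4)
        norms = np.linalg.norm(emb.Y, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)
        assert np.all(emb.eigenvalues <= 1 + 1e-9)

    def test_block_structure_collapses_to_indicator_points(self):
        # three disconnected cliques embed as three coincident point groups
        rng = np.random.default_rng(5)
        A = np.zeros((9, 9))
        for b in range(3):
            s = slice(3 * b, 3 * b + 3)
            A[s, s] = np.exp(-random_symmetric(rng, 3, 0.1))
        np.fill_diagonal(A, 0)
        emb = spectral_embedding(normalized_laplacian(A), k=3)
        for b in range(3):
            block = emb.Y[3 * b:3 * b + 3]
            spread = np.abs(block - block[0]).max()
            assert spread < 1e-6

    def test_k_bounds(self):
        L = np.eye(4)
        with pytest.raises(InvalidParameterError):
            spectral_embedding(L, k=1)
        with pytest.raises(InvalidParameterError):
            spectral_embedding(L, k=5)


def exhaustive_kmeans_objective(Y, k):
    """Global k-means optimum by enumerating every assignment (oracle)."""
    n = len(Y)
    digits = (np.arange(k ** n)[:, None] // k ** np.arange(n)[None, :]) % k
    onehot = (digits[:, :, None] == np.arange(k)).astype(float)
    counts = onehot.sum(axis=1)  # (A, k)
    sums = np.einsum("ank,nd->akd", onehot, Y)
    total = (Y ** 2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        red = np.where(counts > 0, (sums ** 2).sum(axis=2) / counts, 0.0)
    return float((total - red.sum(axis=1)).min())


class TestKMeans:
    def test_degenerate_k(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(7, 3))
        labels, centroids, obj = kmeans(Y, k=7, seed=0)
        assert obj == pytest.approx(0.0, abs=1e-12)
        labels, centroids, obj = kmeans(Y, k=1, seed=0)
        assert np.allclose(centroids[0], Y.mean(axis=0))

    def test_well_separated_triplets_match_exhaustive_search(self):
        rng = np.random.default_rng(7)
        Y = np.concatenate([rng.normal(c, 0.05, size=(3, 2))
                            for c in ([0, 0], [10, 0], [0, 10])])
        labels, _, obj = kmeans(Y, k=3, seed=1)
        assert obj == pytest.approx(exhaustive_kmeans_objective(Y, 3), abs=1e-9)
        expected = np.repeat([0, 1, 2], 3)
        assert rand_index(labels, expected) == 1.0

    def test_objective_non_increasing_within_run(self):
        from polyclust.spectral_clustering import _lloyd

        rng = np.random.default_rng(8)
        Y = rng.normal(size=(40, 3))
        # track the objective across iterations by re-running with caps
        objs = []
        for cap in range(1, 12):
            _, _, obj = _lloyd(Y, 4, np.arange(4), max_iter=cap)
            objs.append(obj)
        assert np.all(np.diff(objs) <= 1e-12)

    def test_k_larger_than_n(self):
        with pytest.raises(InvalidParameterError):
            kmeans(np.zeros((3, 2)), k=4)


class TestPipeline:
    @pytest.mark.parametrize("k", [3, 5, 10, 15])
    def test_linear_model_clusters_are_contiguous_blocks(self, linear_X, k):
        res = spectral_cluster(linear_X, k, seed=0)
        sizes = []
        for c in range(1, k + 1):
            members = np.flatnonzero(res.labels == c)
            assert np.all(np.diff(members) == 1)  # contiguous interval
            sizes.append(len(members))
        assert max(sizes) / min(sizes) < 2  # roughly equal blocks

    def test_duplicate_groups_recovered(self):
        # two groups of duplicated structures, far apart
        X = np.zeros((6, 6))
        X[:3, 3:] = 10.0
        X[3:, :3] = 10.0
        res = spectral_cluster(X, k=2, q=2, seed=0)
        assert rand_index(res.labels, [0, 0, 0, 1, 1, 1]) == 1.0

    def test_deterministic_given_seed(self, sinusoid_X):
        a = spectral_cluster(sinusoid_X, 5, seed=42)
        b = spectral_cluster(sinusoid_X, 5, seed=42)
        assert np.array_equal(a.labels, b.labels)
        assert a.objective == b.objective

    def test_labels_renumbered_temporally(self, linear_X):
        res = spectral_cluster(linear_X, 5, seed=0)
        medians = [np.median(np.flatnonzero(res.labels == c))
                   for c in range(1, 6)]
        assert np.all(np.diff(medians) > 0)

    def test_pipeline_kmeans_matches_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(9)
        hits = 0
        trials = 100
        for _ in range(trials):
            n = int(rng.integers(6, 10))
            X = random_symmetric(rng, n)
            res = spectral_cluster(X, k=3, q=2,
                                   seed=int(rng.integers(2 ** 31)))
            oracle = exhaustive_kmeans_objective(res.embedding.Y, 3)
            if res.objective <= oracle + 1e-9:
                hits += 1
        assert hits >= 95

    def test_sinusoid_sigma_signature(self, sinusoid_X):
        from polyclust.analytic_models import sinusoid_state_centers

        centers = np.array(sinusoid_state_centers(sinusoid_X)) - 1
        sigma = local_scaling(sorted_rows(sinusoid_X), q=10).sigma
        mids = (centers[:-1] + centers[1:]) // 2
        center_mean = np.mean([sigma[c - 50:c + 51].mean() for c in centers])
        gap_mean = np.mean([sigma[m - 50:m + 51].mean() for m in mids])
        assert center_mean < gap_mean
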