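"""Locally-scaled spectral clustering of conformational ensembles.

The pipeline turns a pairwise dissimilarity matrix into a partition:

1. sort each row of the dissimilarity matrix ``X`` ascending;
2. scale locally: ``sigma_i`` = mean distance from structure ``i`` to its
   ``q`` nearest neighbors (averaging over the neighbors, rather than taking
   the single ``q``-th neighbor, makes the method robust to the choice of
   ``q``; default ``q = 10``).  Low sigma marks a densely populated region
   of structure space, high sigma a sparse one;
3. Gaussian affinity ``a_ij = exp(-x_ij^2 / (2 sigma_i sigma_j))``, zero
   diagonal;
4. normalized graph Laplacian ``L = D^(-1/2) A D^(-1/2)``;
5. embed each structure as the corresponding row of the matrix of the top-k
   eigenvectors of ``L``, rows normalized to unit length;
6. k-means (Lloyd) on the embedded points, restarted from random data
   points, keeping the restart with the smallest within-cluster sum of
   squared distances.

Cluster labels are finally renumbered by ascending median frame time, so
cluster 1 is earliest in the trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .containers import InvalidInputError, InvalidParameterError

__all__ = [
    "ScalingVector",
    "SpectralEmbedding",
    "ClusterResult",
    "sorted_rows",
    "local_scaling",
    "affinity_matrix",
    "normalized_laplacian",
    "spectral_embedding",
    "kmeans",
    "spectral_cluster",
]

DEFAULT_Q = 10
DEFAULT_RESTARTS = 10
DEFAULT_MAX_ITER = 30
SIGMA_FLOOR_FACTOR = 1e-12


class DegenerateGraphError(InvalidInputError):
    """An affinity graph with an isolated vertex cannot be normalized."""


@dataclass(frozen=True)
class ScalingVector:
    """Per-structure local density scales sigma and the neighbor count q."""

    sigma: np.ndarray
    q: int


@dataclass(frozen=True)
class SpectralEmbedding:
    """Row-normalized top-k eigenvector embedding and its eigenvalues."""

    Y: np.ndarray
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class ClusterResult:
    """Partition of the frames for one value of k.

    ``labels`` are 1-based cluster ids, renumbered so that clusters are in
    ascending order of median member frame time.  ``objective`` is the
    k-means within-cluster sum of squared distances in the embedding.
    """

    labels: np.ndarray
    k: int
    objective: float
    centroids: np.ndarray
    sigma: ScalingVector | None = None
    embedding: SpectralEmbedding | None = None

    def members(self, cluster_id: int) -> np.ndarray:
        """0-based frame indices belonging to a 1-based cluster id."""
        return np.flatnonzero(self.labels == cluster_id)


def _check_square(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise InvalidInputError(f"expected a square matrix, got shape {X.shape}")
    return X


def sorted_rows(X) -> np.ndarray:
    """Sort each row of the dissimilarity matrix ascending (stable)."""
    return np.sort(_check_square(X), axis=1, kind="stable")


def local_scaling(S, q: int = DEFAULT_Q) -> ScalingVector:
    """Average distance to the q nearest non-self structures, per row.

    ``S`` must be row-sorted.  Entries are floored at a tiny positive value
    (1e-12 times the largest distance) so that duplicated structures do not
    produce a zero scale.
    """
    S = _check_square(S)
    n = S.shape[0]
    if q < 1:
        raise InvalidParameterError(f"q must be >= 1, got {q}")
    if q >= n:
        raise InvalidParameterError(f"q must be < n = {n}, got {q}")
    sigma = S[:, 1:q + 1].mean(axis=1)
    scale = S.max()
    floor = SIGMA_FLOOR_FACTOR * scale if scale > 0 else SIGMA_FLOOR_FACTOR
    return ScalingVector(sigma=np.maximum(sigma, floor), q=q)


def affinity_matrix(X, scaling: ScalingVector) -> np.ndarray:
    """Locally-scaled Gaussian affinity with an exactly zero diagonal."""
    X = _check_square(X)
    sigma = np.asarray(scaling.sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise InvalidParameterError("all scaling parameters must be positive")
    A = np.exp(-(X * X) / (2.0 * np.outer(sigma, sigma)))
    np.fill_diagonal(A, 0.0)
    return A


def normalized_laplacian(A) -> np.ndarray:
    """Symmetric normalization ``L = D^(-1/2) A D^(-1/2)``.

    Raises
    ------
    DegenerateGraphError
        If any vertex has zero degree, naming the first offending frame
        (1-based).
    """
    A = _check_square(A)
    d = A.sum(axis=1)
    if np.any(d <= 0):
        frame = int(np.argmax(d <= 0)) + 1
        raise DegenerateGraphError(
            f"frame {frame} is isolated (zero affinity to all others)"
        )
    inv_sqrt = 1.0 / np.sqrt(d)
    return A * np.outer(inv_sqrt, inv_sqrt)


def spectral_embedding(L, k: int) -> SpectralEmbedding:
    """Top-k eigenvector embedding of the normalized Laplacian.

    Rows are normalized to unit length; a row that is numerically zero is
    left as zeros with a warning.  Eigenvalue ties are resolved by whatever
    orthonormal basis the symmetric solver returns; the downstream k-means
    objective is invariant under orthogonal transformations of tied
    subspaces.
    """
    L = _check_square(L)
    n = L.shape[0]
    if not 2 <= k <= n:
        raise InvalidParameterError(f"k must be in [2, {n}], got {k}")
    vals, vecs = scipy.linalg.eigh(L, subset_by_index=(n - k, n - 1))
    order = np.argsort(vals)[::-1]  # descending
    vals = vals[order]
    Y = vecs[:, order]
    norms = np.linalg.norm(Y, axis=1)
    zero = norms < 1e-300
    if np.any(zero):
        warnings.warn(f"{zero.sum()} embedding rows are zero and stay zero")
        norms[zero] = 1.0
    return SpectralEmbedding(Y=Y / norms[:, None], eigenvalues=vals)


def _lloyd(Y: np.ndarray, k: int, init_idx: np.ndarray,
           max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-means run from the given initial data points."""
    centroids = Y[init_idx].copy()
    labels = np.full(Y.shape[0], -1)
    for _ in range(max_iter):
        d2 = ((Y[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # refill empty clusters with the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = d2[np.arange(len(Y)), new_labels].argmax()
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = Y[labels == c].mean(axis=0)
    d2 = ((Y - centroids[labels]) ** 2).sum()
    return labels, centroids, float(d2)


def kmeans(Y, k: int, restarts: int = DEFAULT_RESTARTS,
           max_iter: int = DEFAULT_MAX_ITER, seed: int | None = 0,
           rng: np.random.Generator | None = None
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Restarted Lloyd k-means on embedded points.

    Each restart initializes the centroids at ``k`` distinct data points
    chosen uniformly at random; iterations stop when labels no longer change
    or after ``max_iter`` sweeps.  Returns ``(labels, centroids, objective)``
    of the restart with the smallest within-cluster sum of squares; labels
    here are raw 0-based (renumbering happens in :func:`spectral_cluster`).
    """
    Y = np.asarray(Y, dtype=np.float64)
    n = Y.shape[0]
    if k > n:
        raise InvalidParameterError(f"k = {k} exceeds the number of points {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        init_idx = rng.choice(n, size=k, replace=False)
        labels, centroids, obj = _lloyd(Y, k, init_idx, max_iter)
        if best is None or obj < best[2]:
            best = (labels, centroids, obj)
    return best


def _renumber_by_time(labels: np.ndarray, frame_times: np.ndarray,
                      k: int) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 1..k by ascending median member frame time."""
    medians = np.array([np.median(frame_times[labels == c]) for c in range(k)])
    order = np.argsort(medians, kind="stable")
    mapping = np.empty(k, dtype=int)
    mapping[order] = np.arange(1, k + 1)
    return mapping[labels], order


def spectral_cluster(X, k: int, q: int = DEFAULT_Q, seed: int = 0,
                     restarts: int = DEFAULT_RESTARTS,
                     max_iter: int = DEFAULT_MAX_ITER,
                     frame_times: np.ndarray | None = None) -> ClusterResult:
    """Full locally-scaled spectral clustering of a dissimilarity matrix.

    Deterministic for a given seed (one seeded generator drives all k-means
    restarts in sequence).  Labels are 1-based and temporally renumbered.
    """
    X = _check_square(X)
    n = X.shape[0]
    if frame_times is None:
        frame_times = np.arange(1, n + 1)
    S = sorted_rows(X)
    scaling = local_scaling(S, q)
    A = affinity_matrix(X, scaling)
    L = normalized_laplacian(A)
    emb = spectral_embedding(L, k)
    rng = np.random.default_rng(seed)
    raw_labels, centroids, obj = kmeans(emb.Y, k, restarts=restarts,
                                        max_iter=max_iter, rng=rng)
    labels, order = _renumber_by_time(raw_labels, np.asarray(frame_times), k)
    return ClusterResult(labels=labels, k=k, objective=obj,
                         centroids=centroids[order], sigma=scaling,
                         embedding=emb)
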