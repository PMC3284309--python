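"""Analytic polymer models: dissimilarity matrices with built-in state structure.

Two benchmark "simulations" are defined directly at the level of the pairwise
dissimilarity matrix, without ever constructing 3D structures:

* **Linear model** — the distance between frames ``i`` and ``j`` is ``|i - j|``.
  The trajectory drifts at constant speed into new regions of structure space
  and contains no meta-stable or transition states.

* **Sinusoid model** — successive frames are separated by a positive increment
  ``cos(6*pi*(u-1)/(n-2)) + z`` with ``z > 1``, so the trajectory still always
  advances, but alternately compresses (dense, meta-stable regions) and
  dilates (sparse, transition regions).  With the default ``z`` slightly above
  one, three meta-stable centers appear where the increment attains its local
  minima, with transition regions at the start, end, and between the centers.

Both matrices are exact, symmetric, nonnegative, and zero on the diagonal.
Frame indices in all formulas and reported centers are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import InvalidInputError, InvalidParameterError

DEFAULT_Z = 1.01


@dataclass(frozen=True)
class AnalyticModelParams:
    """Parameters of the analytic models.

    Parameters
    ----------
    n : int
        Number of frames; must be at least 3.
    z : float
        Sinusoid offset keeping every frame-to-frame increment positive;
        must exceed 1.  Ignored by the linear model.
    """

    n: int
    z: float = DEFAULT_Z

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InvalidParameterError(f"n must be >= 3, got {self.n}")


def linear_dissimilarity(params: AnalyticModelParams) -> np.ndarray:
    """Dissimilarity matrix of the linear model: ``X[i, j] = |i - j|``.

    Returns an ``(n, n)`` float array (0-based storage of the 1-based frame
    grid; the entry for frames ``i`` and ``j`` is identical either way).
    """
    idx = np.arange(params.n, dtype=np.float64)
    return np.abs(idx[:, None] - idx[None, :])


def _sinusoid_increments(n: int, z: float) -> np.ndarray:
    """Per-step increments ``d(t) = cos(6*pi*(t-1)/(n-2)) + z`` for t=1..n-1."""
    t = np.arange(1, n, dtype=np.float64)
    return np.cos(6.0 * np.pi * (t - 1.0) / (n - 2.0)) + z


def sinusoid_dissimilarity(params: AnalyticModelParams) -> np.ndarray:
    """Dissimilarity matrix of the sinusoid model.

    The entry for frames ``i`` and ``j`` is the absolute difference of the
    cumulative sums of the positive increments
    ``cos(6*pi*(u-1)/(n-2)) + z`` for ``u = 1 .. i-1`` and ``u = 1 .. j-1``.
    Because every increment is positive for ``z > 1``, each row increases
    strictly with distance from the diagonal.

    Raises
    ------
    InvalidParameterError
        If ``z <= 1``.
    """
    if params.z <= 1.0:
        raise InvalidParameterError(
            f"sinusoid model requires z > 1, got z={params.z}"
        )
    inc = _sinusoid_increments(params.n, params.z)
    # position of frame t (1-based) along the 1D "reaction coordinate"
    pos = np.concatenate([[0.0], np.cumsum(inc)])
    return np.abs(pos[:, None] - pos[None, :])


def sinusoid_state_centers(X: np.ndarray) -> list[int]:
    """Locate meta-stable centers of a sinusoid-model matrix.

    The centers are the 1-based frame indices ``t`` at which the successive
    increment ``d(t) = X(1, t+1) - X(1, t)`` is a strict local minimum
    (smaller than both neighbors; plateau ties broken by the smallest index).
    For the default model (``n=1000, z=1.01``) there are exactly three,
    at frames 167, 500 and 833.

    Raises
    ------
    InvalidInputError
        If the first row of ``X`` is not strictly increasing, i.e. the matrix
        was not produced by a sinusoid-type model.
    """
    X = np.asarray(X, dtype=np.float64)
    d = np.diff(X[0])
    if np.any(d <= 0):
        raise InvalidInputError(
            "input is not a sinusoid-model matrix: first row is not "
            "strictly increasing"
        )
    centers = [
        t + 1  # 0-based offset in d -> 1-based frame index t
        for t in range(1, len(d) - 1)
        if d[t] < d[t - 1] and d[t] < d[t + 1]
    ]
    return centers


def save_matrix_csv(X: np.ndarray, path) -> None:
    """Write a dissimilarity matrix as header-less CSV rows of floats."""
    np.savetxt(path, np.asarray(X, dtype=np.float64), delimiter=",")


def load_matrix_csv(path) -> np.ndarray:
    """Read a dissimilarity matrix written by :func:`save_matrix_csv`."""
    X = np.loadtxt(path, delimiter=",", dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise InvalidInputError(f"expected a square matrix, got shape {X.shape}")
    return X
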