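"""Pairwise structural comparison (superposed RMSD) and geometric observables.

RMSD between two conformations is minimized over all proper rigid-body
superpositions (rotations with determinant +1 plus translations; reflections
are excluded, since mirror-image polymers are distinct molecules).  The
optimal rotation is obtained by the Kabsch/SVD construction with the standard
sign correction on the smallest singular value.  All particles are weighted
equally (the models are C-alpha-trace analogues).

The full ``n x n`` dissimilarity matrix is computed in blocks of frame pairs
with batched 3x3 SVDs, and is held densely in memory (fine up to n ~ 10^4).
"""

from __future__ import annotations

import numpy as np

from .containers import InvalidInputError, StructureEnsemble

__all__ = [
    "superpose",
    "rmsd",
    "pairwise_rmsd_matrix",
    "rmsd_to_reference",
    "radius_of_gyration",
]


def _as_structure(P) -> np.ndarray:
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != 3:
        raise InvalidInputError(f"structure must have shape (particles, 3), got {P.shape}")
    return P


def superpose(P, Q) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal proper rigid superposition of ``Q`` onto ``P``.

    Returns ``(rmsd, rotation, translation)`` such that
    ``Q @ rotation.T + translation`` minimizes the RMSD to ``P`` over all
    rotations with determinant +1 and translations.

    Raises
    ------
    InvalidInputError
        If the particle counts differ.
    """
    P, Q = _as_structure(P), _as_structure(Q)
    if P.shape != Q.shape:
        raise InvalidInputError(
            f"particle count mismatch: {P.shape[0]} vs {Q.shape[0]}"
        )
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = Q0.T @ P0  # covariance mapping Q-frame onto P-frame
    U, S, Vt = np.linalg.svd(H)
    d = 1.0 if np.linalg.det(U) * np.linalg.det(Vt) >= 0 else -1.0
    # flip the smallest singular value's axis to stay in SO(3)
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    # explicit residual: numerically exact zero for congruent structures
    resid = P0 - Q0 @ R.T
    value = float(np.sqrt((resid * resid).sum() / P.shape[0]))
    translation = pc - qc @ R.T
    return value, R, translation


def rmsd(P, Q) -> float:
    """Minimal RMSD between two structures (see :func:`superpose`)."""
    return superpose(P, Q)[0]


def pairwise_rmsd_matrix(ensemble: StructureEnsemble,
                         block: int = 64) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between every pair of frames.

    Each unordered pair is computed once; the diagonal is exactly zero.
    """
    if ensemble.n_frames < 2:
        raise InvalidInputError("need at least 2 frames for a pairwise matrix")
    coords = ensemble.coordinates
    n, m, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    X = np.zeros((n, n))
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        for j0 in range(i0, n, block):
            j1 = min(j0 + block, n)
            # cross-covariance for every (i, j) pair in the block
            H = np.einsum("jpa,ipb->ijab", centered[j0:j1], centered[i0:i1])
            U, _, Vt = np.linalg.svd(H)
            sign = np.where(np.linalg.det(H) < 0, -1.0, 1.0)
            U[..., :, 2] *= sign[..., None]
            R = np.swapaxes(U @ Vt, -1, -2)
            rotated = np.einsum("ijab,jpb->ijpa", R, centered[j0:j1])
            resid = centered[i0:i1, None] - rotated
            X[i0:i1, j0:j1] = np.sqrt(
                np.einsum("ijpa,ijpa->ij", resid, resid) / m
            )
    iu = np.triu_indices(n, 1)
    X[(iu[1], iu[0])] = X[iu]
    np.fill_diagonal(X, 0.0)
    return X


def rmsd_to_reference(ensemble: StructureEnsemble, ref) -> np.ndarray:
    """Superposed RMSD of every frame to a fixed reference structure."""
    ref = _as_structure(ref)
    if ref.shape[0] != ensemble.n_particles:
        raise InvalidInputError(
            f"particle count mismatch: ensemble has {ensemble.n_particles}, "
            f"reference has {ref.shape[0]}"
        )
    return np.array([rmsd(frame, ref) for frame in ensemble.coordinates])


def radius_of_gyration(structure) -> float:
    """Root-mean-squared distance of particles from their centroid."""
    P = _as_structure(structure)
    centered = P - P.mean(axis=0)
    return float(np.sqrt((centered * centered).sum() / P.shape[0]))


def radius_of_gyration_series(ensemble: StructureEnsemble) -> np.ndarray:
    """Per-frame radius of gyration."""
    centered = ensemble.coordinates - ensemble.coordinates.mean(axis=1, keepdims=True)
    return np.sqrt(np.einsum("fpc,fpc->f", centered, centered) / ensemble.n_particles)
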