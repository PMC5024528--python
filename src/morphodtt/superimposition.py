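"""Generalized Procrustes Analysis (GPA).

Superimposition removes the nuisance parameters of digitization —
translation, scale and rotation — so that only shape differences remain.
Every specimen is centred, scaled to unit centroid size, and rotated (proper
rotations only, no reflection) onto an iteratively re-estimated consensus.
Semilandmarks are treated as ordinary fixed landmarks; no sliding is
performed, because sliding can introduce substantial artificial deformation
in heterogeneous samples.  Aligned coordinates are used directly (no tangent
projection); at the small shape variances typical of one skull template the
difference is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LandmarkConfiguration

__all__ = [
    "DegenerateShapeError",
    "AlignedShapeSet",
    "center_and_scale",
    "centroid_size",
    "optimal_rotation",
    "canonical_rotation",
    "GeneralizedProcrustes",
    "gpa",
]


class DegenerateShapeError(ValueError):
    """All landmarks coincident: centroid size zero, shape undefined."""


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared distances of the landmarks from their centroid."""
    coords = np.asarray(coords, dtype=float)
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Centre at the origin and scale to unit centroid size.

    Returns the transformed coordinates and the original centroid size.
    Raises :class:`DegenerateShapeError` if all points coincide.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 landmarks")
    centred = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centred**2)))
    if size < 1e-12 * max(1.0, np.abs(coords).max()):
        raise DegenerateShapeError("all landmarks coincident")
    return centred / size, size

def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper 2x2 rotation R minimizing ||A - B @ R|| for centred shapes.

    Reflections are excluded (determinant is forced to +1): all specimens
    are digitized in the same lateral view, so a mirror fit would be a
    digitization error, not shape similarity.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"point-count mismatch: {A.shape} vs {B.shape}")
    # Kabsch with the proper-rotation sign correction
    H = B.T @ A
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation taking a consensus to its canonical orientation.

    GPA determines the aligned set only up to one common rotation; to make
    results independent of specimen order and of the digitized orientation,
    the consensus is rotated so its major principal axis lies along x, with
    the 180-degree ambiguity resolved by the sign of the third moment along
    x (falling back to the y moment, then to the first landmark).
    """
    M = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    if np.linalg.det(evecs) < 0:
        evecs[:, 1] = -evecs[:, 1]
    rotated = consensus @ evecs
    for moment in (np.sum(rotated[:, 0] ** 3), np.sum(rotated[:, 1] ** 3), rotated[0, 0]):
        if abs(moment) > 1e-12:
            if moment < 0:
                evecs = -evecs  # 180-degree flip (proper rotation in 2D)
            break
    return evecs


@dataclass
class AlignedShapeSet:
    """GPA result: consensus, aligned coordinates, residuals, sizes.

    ``residuals`` is the specimens x 2k matrix of aligned coordinates minus
    their sample mean, flattened (x1, y1, x2, y2, ...).  The sample mean of
    the aligned specimens equals the unit-size consensus up to a uniform
    scale factor of order 1 - variance/2, so residuals are taken about the
    mean itself: they then sum exactly to zero, which is what a covariance
    matrix assumes.
    """

    taxa: list[str]
    consensus: np.ndarray
    aligned: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray

    @property
    def mean_shape(self) -> np.ndarray:
        return self.aligned.mean(axis=0)

    @property
    def residuals(self) -> np.ndarray:
        return (self.aligned - self.mean_shape).reshape(len(self.taxa), -1)


class GeneralizedProcrustes(TransformerMixin, BaseEstimator):
    """Generalized Procrustes superimposition as a scikit-learn transformer.

    ``fit`` runs the iterative GPA on a stack of configurations: all
    specimens are centred and scaled to unit centroid size, rotated onto the
    current consensus, and the consensus (the specimen mean, rescaled to
    unit size) is re-estimated until its root-mean-square change falls below
    ``tol``.  ``transform`` aligns configurations onto the fitted consensus
    and returns flattened Procrustes residuals, the raw material of shape
    PCA.

    Parameters
    ----------
    tol : float, default 1e-10
        Convergence threshold on the consensus RMS change.
    max_iter : int, default 100
        Iteration cap; exceeding it raises with the last change magnitude.

    Attributes
    ----------
    consensus_ : (k, 2) ndarray
        Mean shape, centred at the origin with unit centroid size.
    aligned_ : (n, k, 2) ndarray
        Training specimens after superimposition.
    centroid_sizes_ : (n,) ndarray
        Original centroid sizes (the size variable removed by GPA).
    n_iter_ : int
        Iterations until convergence.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _as_stack(X) -> np.ndarray:
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], LandmarkConfiguration):
            counts = {c.n_landmarks for c in X}
            if len(counts) > 1:
                raise ValueError(f"landmark counts differ: {sorted(counts)}")
            return np.stack([c.coords for c in X])
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError(f"expected (n, k, 2) coordinate stack; got {X.shape}")
        return X

    def fit(self, X, y=None):
        """Run GPA on ``X`` (list of configurations or (n, k, 2) array)."""
        stack = self._as_stack(X)
        n = stack.shape[0]
        if n < 2:
            raise ValueError("GPA needs at least 2 configurations")
        if not np.all(np.isfinite(stack)):
            raise ValueError("non-finite coordinates")
        unit = np.empty_like(stack)
        sizes = np.empty(n)
        for i in range(n):
            unit[i], sizes[i] = center_and_scale(stack[i])
        # initial consensus: first specimen (any choice converges to the
        # same fixed point; order-invariance is covered by the tests)
        consensus = unit[0].copy()
        aligned = unit.copy()
        last_change = np.inf
        for iteration in range(1, self.max_iter + 1):
            for i in range(n):
                aligned[i] = unit[i] @ optimal_rotation(consensus, unit[i])
            new_consensus = aligned.mean(axis=0)
            new_consensus -= new_consensus.mean(axis=0)
            norm = np.sqrt(np.sum(new_consensus**2))
            if norm < 1e-12:
                raise DegenerateShapeError("consensus collapsed to a point")
            new_consensus /= norm
            last_change = float(
                np.sqrt(np.mean((new_consensus - consensus) ** 2))
            )
            consensus = new_consensus
            if last_change < self.tol:
                break
        else:
            raise RuntimeError(
                f"GPA did not converge in {self.max_iter} iterations "
                f"(last consensus RMS change {last_change:.3e})"
            )
        # canonical frame, then a final pass aligning every specimen to it
        R = canonical_rotation(consensus)
        consensus = consensus @ R
        for i in range(n):
            aligned[i] = unit[i] @ optimal_rotation(consensus, unit[i])
        self.consensus_ = consensus
        self.aligned_ = aligned
        # residual reference: the raw specimen mean (parallel to the unit
        # consensus, shorter by ~variance/2); residuals about it sum to zero
        self.mean_ = aligned.mean(axis=0)
        self.centroid_sizes_ = sizes
        self.n_iter_ = iteration
        self.n_landmarks_ = stack.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Align ``X`` to the fitted consensus; return (n, 2k) residuals."""
        if not hasattr(self, "consensus_"):
            raise ValueError("GeneralizedProcrustes is not fitted")
        stack = self._as_stack(X)
        if stack.shape[1] != self.n_landmarks_:
            raise ValueError(
                f"landmark count {stack.shape[1]} != fitted {self.n_landmarks_}"
            )
        out = np.empty_like(stack)
        for i in range(stack.shape[0]):
            u, _ = center_and_scale(stack[i])
            out[i] = u @ optimal_rotation(self.consensus_, u)
        return (out - self.mean_).reshape(stack.shape[0], -1)

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return (self.aligned_ - self.mean_).reshape(self.aligned_.shape[0], -1)


def gpa(
    configs: list[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Functional wrapper over :class:`GeneralizedProcrustes`."""
    est = GeneralizedProcrustes(tol=tol, max_iter=max_iter).fit(configs)
    if isinstance(configs, (list, tuple)) and configs and isinstance(
        configs[0], LandmarkConfiguration
    ):
        taxa = [c.taxon for c in configs]
    else:
        taxa = [f"specimen_{i}" for i in range(est.aligned_.shape[0])]
    return AlignedShapeSet(
        taxa=taxa,
        consensus=est.consensus_,
        aligned=est.aligned_,
        centroid_sizes=est.centroid_sizes_,
    )
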