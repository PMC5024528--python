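"""Shape ordination: covariance-matrix PCA of Procrustes residuals and
broken-stick selection of the significant components.

The PCA is an eigendecomposition of the (n-1)-divisor sample covariance
matrix of the residuals; scores are the centred residuals projected on the
eigenvectors.  Eigenvector signs follow a deterministic rule (the
largest-magnitude loading of each component is positive) so that scores are
reproducible across linear-algebra backends; every downstream statistic is
sign-invariant regardless.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "covariance_matrix",
    "ShapePCA",
    "pca",
    "broken_stick_proportions",
    "broken_stick",
]


def covariance_matrix(residuals: np.ndarray) -> np.ndarray:
    """Sample covariance matrix of the rows, divisor (n - 1)."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    centred = residuals - residuals.mean(axis=0)
    return centred.T @ centred / (residuals.shape[0] - 1)


class ShapePCA(TransformerMixin, BaseEstimator):
    """Principal component analysis of a residual matrix.

    Parameters
    ----------
    n_components : int or None
        Components to keep; None keeps all with positive variance
        (min(n - 1, p)).

    Attributes
    ----------
    mean_ : (p,) ndarray
        Column means removed before projection.
    components_ : (m, p) ndarray
        Orthonormal eigenvectors (rows), descending eigenvalue order.
    explained_variance_ : (m,) ndarray
        Eigenvalues of the (n-1)-divisor covariance matrix.
    explained_variance_ratio_ : (m,) ndarray
        Eigenvalue / total variance; divisor-invariant.
    scores_ : (n, m) ndarray
        Training-data PC scores.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("PCA needs a 2D matrix with at least 3 rows")
        n, p = X.shape
        self.mean_ = X.mean(axis=0)
        centred = X - self.mean_
        cov = centred.T @ centred / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # deterministic sign: largest-|loading| entry of each PC positive
        for j in range(evecs.shape[1]):
            i_max = np.argmax(np.abs(evecs[:, j]))
            if evecs[i_max, j] < 0:
                evecs[:, j] = -evecs[:, j]
        m = self.n_components if self.n_components is not None else min(n - 1, p)
        m = min(m, evecs.shape[1])
        self.total_variance_ = float(evals.sum())
        if self.total_variance_ <= 0:
            raise ValueError("zero total variance: all rows identical")
        self.explained_variance_ = evals[:m]
        self.explained_variance_ratio_ = evals[:m] / self.total_variance_
        self.components_ = evecs[:, :m].T
        self.scores_ = centred @ evecs[:, :m]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ValueError("ShapePCA is not fitted")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Map scores back to residual space (mean added back)."""
        return np.asarray(scores, dtype=float) @ self.components_ + self.mean_


def pca(residuals: np.ndarray, n_components: int | None = None) -> ShapePCA:
    """Fit a :class:`ShapePCA` on a residual matrix."""
    return ShapePCA(n_components=n_components).fit(residuals)


def broken_stick_proportions(p: int) -> np.ndarray:
    """Broken-stick null proportions b_i = (1/p) * sum_{j=i..p} 1/j."""
    if p < 1:
        raise ValueError("need at least one eigenvalue")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick(eigenvalues: np.ndarray) -> int:
    """Number of leading components exceeding the broken-stick expectation.

    Returns the largest m such that the observed eigenvalue proportion
    strictly exceeds the broken-stick proportion for every component up to
    m (a contiguous block from PC1; 0 if PC1 already fails).
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if eigenvalues.size < 1:
        raise ValueError("need at least one eigenvalue")
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    observed = eigenvalues / total
    expected = broken_stick_proportions(eigenvalues.size)
    m = 0
    for obs, exp in zip(observed, expected):
        if obs > exp:
            m += 1
        else:
            break
    return m
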