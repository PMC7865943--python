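"""Normalization, PCA reduction and supervised locality preserving projection.

The adaptation pipeline first z-scores every feature over the pooled
source+target columns (the setting is transductive: both domains are in
hand when the projection is learned), reduces to k dimensions with PCA,
then learns a supervised locality preserving projection (SLPP): a linear
map P that pulls same-class samples together.  With the binary same-class
similarity S, degree matrix D (D_ii = sum_j S_ij) and graph Laplacian
L = D - S, P solves the generalized eigenproblem

    X_l D X_l^T p = lambda (X_l L X_l^T + I) p

over the labeled stack X_l, keeping the eigenvectors of the m largest
eigenvalues.  Both matrices are symmetrized and the right-hand side gets a
small unconditional ridge before the solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each column > 0."""
    V = V.copy()
    idx = np.abs(V).argmax(axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


@dataclass
class NormalizationModel:
    """Stored per-feature z-score statistics (zero-variance rows map to 0)."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        inv = np.where(self.std > 1e-12, 1.0 / np.where(self.std > 1e-12, self.std, 1.0), 0.0)
        return (X - self.mean[:, None]) * inv[:, None]


def normalize(X: np.ndarray):
    """Row-wise z-score of a d x n matrix; returns (Xn, model)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a d x n matrix with n >= 2")
    model = NormalizationModel(mean=X.mean(axis=1), std=X.std(axis=1))
    return model.transform(X), model


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # d x k, orthonormal columns
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.components.T @ (X - self.mean[:, None])


def pca_fit_transform(X: np.ndarray, k: int):
    """Top-k principal axes of the sample covariance of the columns of X.

    Returns ``(model, Xbar)`` with ``Xbar`` the k x n projected data,
    ordered by decreasing explained variance.
    """
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    if not 1 <= k <= min(d, n):
        raise ValueError(f"k must lie in 1..min(d, n) = {min(d, n)}, got {k}")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    cov = (Xc @ Xc.T) / max(n - 1, 1)
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    order = np.argsort(w)[::-1][:k]
    comps = _fix_signs(V[:, order])
    model = PCAModel(mean=mean, components=comps, explained_variance=np.maximum(w[order], 0.0))
    return model, comps.T @ Xc


def build_similarity(labels) -> np.ndarray:
    """Binary same-class similarity matrix: S_ij = 1 iff y_i = y_j."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("labels must be non-empty")
    return np.equal.outer(y, y).astype(float)


@dataclass
class SLPPModel:
    P: np.ndarray  # k x m projection
    eigenvalues: np.ndarray  # descending

    @property
    def m(self) -> int:
        return self.P.shape[1]

    def project(self, Xbar: np.ndarray) -> np.ndarray:
        return self.P.T @ Xbar


def slpp_fit(Xl: np.ndarray, labels, m: int | None = None, ridge: float = 1e-8) -> SLPPModel:
    """Fit the supervised locality preserving projection on labeled data.

    ``Xl`` is the k x n_l (PCA-reduced) labeled stack.  ``m`` defaults to k
    (no further reduction beyond PCA).  Eigenvalues are sorted descending
    and eigenvector signs follow the largest-entry-positive convention.
    """
    Xl = np.asarray(Xl, dtype=float)
    k, nl = Xl.shape
    if nl < 2:
        raise ValueError("need at least 2 labeled samples")
    m = k if m is None else m
    if not 1 <= m <= k:
        raise ValueError(f"m must lie in 1..k={k}, got {m}")
    S = build_similarity(labels)
    if S.shape[0] != nl:
        raise ValueError("labels length must match the number of columns")
    Dv = S.sum(axis=1)
    A = (Xl * Dv) @ Xl.T  # X_l D X_l^T
    L = np.diag(Dv) - S
    B = Xl @ L @ Xl.T + np.eye(k)
    A = (A + A.T) / 2
    B = (B + B.T) / 2 + ridge * np.eye(k)
    try:
        w, V = scipy.linalg.eigh(A, B)
    except scipy.linalg.LinAlgError:
        warnings.warn("right-hand matrix numerically singular; ridge increased", stacklevel=2)
        B += 1e-6 * np.eye(k)
        w, V = scipy.linalg.eigh(A, B)
    order = np.argsort(w)[::-1][:m]
    return SLPPModel(P=_fix_signs(V[:, order]), eigenvalues=w[order])
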