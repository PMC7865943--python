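"""Improved pseudo-label generation for the unlabeled target domain.

Target samples are labeled in the SLPP subspace by combining two scorers:

* nearest class prototype (NCP): a softmax over negative Euclidean
  distances to the per-class means of the projected source samples;
* structured prediction (SP): K-means on the projected target samples with
  cluster centers initialized at the source prototypes (each cluster keeps
  the class identity of its initializing prototype), scored by the same
  softmax against the final centers.

The combined per-class score is the element-wise maximum of the two
probability rows and the pseudo-label is its argmax (ties go to the lowest
class index).  The full improved-pseudo-label pass projects with a
source-only SLPP first, assigns provisional labels, refits the projection
on source plus pseudo-labeled target, and labels again.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .subspace import SLPPModel, pca_fit_transform, slpp_fit


@dataclass
class PrototypeSet:
    """Per-class mean vectors in the projected subspace (class-ordered)."""

    means: np.ndarray  # C x m
    classes: np.ndarray  # the 1-based class codes, ascending


@dataclass
class PseudoLabels:
    labels: np.ndarray  # 1-based class codes, length nt
    probs: np.ndarray  # nt x C combined scores (not renormalized)
    provenance: np.ndarray  # "NCP" or "SP" winner per sample
    initial_labels: np.ndarray | None = None  # provisional first-pass labels


def project(P, Xbar_s: np.ndarray, Xbar_t: np.ndarray):
    """Apply the learned projection to both domains: Z = P^T Xbar."""
    Pm = P.P if isinstance(P, SLPPModel) else np.asarray(P, dtype=float)
    Xbar_s = np.asarray(Xbar_s, dtype=float)
    Xbar_t = np.asarray(Xbar_t, dtype=float)
    if Xbar_s.shape[0] != Pm.shape[0] or Xbar_t.shape[0] != Pm.shape[0]:
        raise ValueError("projection and data dimensionalities do not match")
    return Pm.T @ Xbar_s, Pm.T @ Xbar_t


def class_prototypes(Zs: np.ndarray, ys, n_classes: int | None = None) -> PrototypeSet:
    """Mean projected source vector per class; every class must appear."""
    ys = np.asarray(ys, dtype=int)
    C = int(n_classes or ys.max())
    means = np.empty((C, Zs.shape[0]))
    for c in range(1, C + 1):
        mask = ys == c
        if not mask.any():
            raise ValueError(f"class {c} absent from the source labels")
        means[c - 1] = Zs[:, mask].mean(axis=1)
    return PrototypeSet(means=means, classes=np.arange(1, C + 1))


def _softmax_neg_dist(Zt: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Rows: softmax over classes of exp(-||z_t - center_y||)."""
    d = cdist(Zt.T, centers)  # nt x C Euclidean distances
    s = -d
    s -= s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def ncp_probabilities(Zt: np.ndarray, prototypes: PrototypeSet) -> np.ndarray:
    """Nearest-class-prototype class probabilities (rows sum to 1)."""
    return _softmax_neg_dist(Zt, prototypes.means)


def lloyd_kmeans(points: np.ndarray, centers: np.ndarray, max_iter: int = 100, tol: float = 1e-6):
    """Deterministic Lloyd iterations from fixed initial centers.

    An empty cluster keeps (freezes) its current center.  Returns the
    final centers, assignments and the per-iteration objective (sum of
    squared distances to the assigned center, evaluated after each
    assignment step) for monotonicity diagnostics.
    """
    centers = np.asarray(centers, dtype=float).copy()
    objective = []
    assign = None
    for _ in range(max_iter):
        d2 = cdist(points, centers, metric="sqeuclidean")
        assign = d2.argmin(axis=1)
        objective.append(float(d2[np.arange(len(points)), assign].sum()))
        new = centers.copy()
        for c in range(centers.shape[0]):
            mask = assign == c
            if mask.any():
                new[c] = points[mask].mean(axis=0)
        shift = np.linalg.norm(new - centers, axis=1).max()
        centers = new
        if shift <= tol:
            break
    return centers, assign, objective


def sp_probabilities(
    Zt: np.ndarray,
    prototypes: PrototypeSet,
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """Structured-prediction probabilities from prototype-seeded K-means.

    Cluster identity is inherited from the initializing prototype and never
    re-matched.  Returns ``(p2, centers)`` with centers as a PrototypeSet
    of the final target cluster centers.
    """
    nt = Zt.shape[1]
    if nt < 1:
        raise ValueError("need at least one target sample")
    C = prototypes.means.shape[0]
    # nt < C is allowed: the unmatched clusters simply stay frozen at their
    # initializing prototypes (a lone target point joins its nearest one).
    centers, assign, _ = lloyd_kmeans(Zt.T, prototypes.means, max_iter=max_iter, tol=tol)
    empty = [c + 1 for c in range(C) if not np.any(assign == c)]
    if empty:
        warnings.warn(f"empty K-means cluster(s) {empty}: centers frozen at initialization", stacklevel=2)
    target_centers = PrototypeSet(means=centers, classes=prototypes.classes.copy())
    return _softmax_neg_dist(Zt, centers), target_centers


def combine(p1: np.ndarray, p2: np.ndarray) -> PseudoLabels:
    """Element-wise max of the two scorers; argmax with lowest-index ties."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p1 and p2 must have identical shapes")
    p = np.maximum(p1, p2)
    labels = p.argmax(axis=1) + 1  # argmax takes the first (lowest) index on ties
    rows = np.arange(p.shape[0])
    winner = np.where(p1[rows, labels - 1] >= p2[rows, labels - 1], "NCP", "SP")
    return PseudoLabels(labels=labels, probs=p, provenance=winner)


def _label_once(model: SLPPModel, Xbar_s, Xbar_t, ys, n_classes) -> PseudoLabels:
    Zs, Zt = project(model, Xbar_s, Xbar_t)
    protos = class_prototypes(Zs, ys, n_classes)
    p1 = ncp_probabilities(Zt, protos)
    p2, _ = sp_probabilities(Zt, protos)
    return combine(p1, p2)


def improved_pseudo_labels(
    Xs: np.ndarray,
    ys,
    Xt: np.ndarray,
    k: int | None = None,
    m: int | None = None,
    n_classes: int | None = None,
):
    """Two-pass improved pseudo-labels for normalized feature matrices.

    PCA is fit on the pooled source+target columns; the first SLPP uses
    source data only to produce provisional labels, the second refits on
    source plus pseudo-labeled target.  Returns ``(PseudoLabels, SLPPModel)``
    with the provisional pass stored in ``initial_labels``.
    """
    Xs = np.asarray(Xs, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    ys = np.asarray(ys, dtype=int)
    d, ns = Xs.shape
    nt = Xt.shape[1]
    n = ns + nt
    C = int(n_classes or ys.max())
    if k is None:
        k = min(128, d, n - 1)
    X = np.hstack([Xs, Xt])
    _, Xbar = pca_fit_transform(X, k)
    Xbar_s, Xbar_t = Xbar[:, :ns], Xbar[:, ns:]
    P0 = slpp_fit(Xbar_s, ys, m=m)
    pl0 = _label_once(P0, Xbar_s, Xbar_t, ys, C)
    P1 = slpp_fit(
        np.hstack([Xbar_s, Xbar_t]), np.concatenate([ys, pl0.labels]), m=m
    )
    pl1 = _label_once(P1, Xbar_s, Xbar_t, ys, C)
    pl1.initial_labels = pl0.labels
    return pl1, P1
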