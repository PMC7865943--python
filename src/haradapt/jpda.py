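"""Joint-probability discriminative MMD domain adaptation.

The adaptation seeks a linear map A (d x p) under which the class-wise
joint distributions of source and target align.  With one-hot label
matrices Ys (ns x C) and pseudo-labels Yt (nt x C), the same-class
coupling matrices are Ns = Ys/ns, Nt = Yt/nt, and the cross-class ones
Ms = Fs/ns, Mt = Ft/nt, where Fs repeats each class column C-1 times and
Ft stacks, for each class c, all non-c columns in ascending class order
(both are n x C(C-1)).  The quadratic forms

    Rmin = [[Ns Ns^T, -Ns Nt^T], [-Nt Ns^T, Nt Nt^T]]
    Rmax = [[Ms Ms^T, -Ms Mt^T], [-Mt Ms^T, Mt Mt^T]]

measure same-class discrepancy (to minimize) and cross-class discrepancy
(to maximize).  With the centering matrix H = I - 1/n (all-entries-1/n
matrix subtracted), the stationarity condition is the generalized
eigenproblem

    (X (Rmin - mu*Rmax) X^T + lambda*I) a = eta * X H X^T a

and A collects the p trailing (smallest-eigenvalue) eigenvectors.

The full driver alternates pseudo-label refinement with this solve: the
first iteration uses the improved pseudo-labels (SLPP + NCP/SP), later
iterations rebuild Rmin/Rmax from the current labels, re-solve for A, and
relabel the target with a nearest-neighbour classifier trained on the
projected source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.neighbors import KNeighborsClassifier

from .pseudo_label import improved_pseudo_labels
from .subspace import _fix_signs, normalize


@dataclass(frozen=True)
class JPDAConfig:
    """Knobs of the adaptation loop.

    mu trades off the cross-class (discriminative) term against the
    same-class alignment term; lambda regularizes A.  Both default to 0.1.
    p is the adapted subspace dimensionality (default min(20, d, n-1):
    the generalized eigenvectors are scatter-whitened, so a large p keeps
    near-noise directions at unit scale and degrades the nearest-neighbour
    classifier), T the number of outer iterations, knn_k the neighbour
    count of the classifier f, and k/m the PCA/SLPP dimensionalities of
    the pseudo-label stage.
    """

    mu: float = 0.1
    lam: float = 0.1
    p: int | None = None
    T: int = 10
    knn_k: int = 1
    pca_k: int | None = None
    slpp_m: int | None = None
    n_classes: int | None = None
    ridge: float = 1e-8

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class IPLJPDAResult:
    labels: np.ndarray  # final target labels, 1-based codes
    history: list  # per-iteration label arrays (length T)
    mmd: list  # per-iteration same-class joint-MMD diagnostic
    A: np.ndarray | None  # final adaptation map (None when T == 1)
    initial_labels: np.ndarray  # provisional labels of the first pass
    accuracy_history: list | None = None  # filled when y_true is supplied


def one_hot(labels, C: int) -> np.ndarray:
    """n x C one-hot matrix from 1-based class codes."""
    y = np.asarray(labels, dtype=int)
    if y.size and (y.min() < 1 or y.max() > C):
        raise ValueError(f"labels must lie in 1..{C}")
    out = np.zeros((len(y), C))
    out[np.arange(len(y)), y - 1] = 1.0
    return out


def build_F(Ys: np.ndarray, Yt: np.ndarray):
    """Cross-class label expansions Fs, Ft of width C(C-1).

    Block c of Fs repeats class-c's column C-1 times; block c of Ft takes
    the columns of Yt for every class except c, in ascending class order.
    """
    C = Ys.shape[1]
    if Yt.shape[1] != C:
        raise ValueError("Ys and Yt must have the same number of classes")
    if C < 2:
        raise ValueError("the discriminative term needs C >= 2 classes")
    Fs = np.concatenate([np.tile(Ys[:, [c]], (1, C - 1)) for c in range(C)], axis=1)
    Ft = np.concatenate(
        [Yt[:, [j for j in range(C) if j != c]] for c in range(C)], axis=1
    )
    return Fs, Ft


def build_R(Ys: np.ndarray, Yt: np.ndarray):
    """Same-class (Rmin) and cross-class (Rmax) joint-probability kernels."""
    ns, nt = Ys.shape[0], Yt.shape[0]
    Fs, Ft = build_F(Ys, Yt)
    Ns, Nt = Ys / ns, Yt / nt
    Ms, Mt = Fs / ns, Ft / nt

    def _blocks(U, V):
        return np.block([[U @ U.T, -U @ V.T], [-V @ U.T, V @ V.T]])

    return _blocks(Ns, Nt), _blocks(Ms, Mt)


def jpda_step(
    X: np.ndarray,
    Ys: np.ndarray,
    Yt: np.ndarray,
    mu: float = 0.1,
    lam: float = 0.1,
    p: int | None = None,
    ridge: float = 1e-8,
):
    """One adaptation solve; X is the column-stacked [Xs, Xt] (d x n).

    Returns ``(A, eigenvalues)`` with A the d x p matrix of the trailing
    generalized eigenvectors (ascending eigenvalues, sign-normalized).
    """
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    if Ys.shape[0] + Yt.shape[0] != n:
        raise ValueError("label rows must sum to the number of columns of X")
    if p is None:
        p = min(20, d, n - 1)
    if not 1 <= p <= d:
        raise ValueError(f"p must lie in 1..d={d}")
    Rmin, Rmax = build_R(Ys, Yt)
    lhs = X @ (Rmin - mu * Rmax) @ X.T + lam * np.eye(d)
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    rhs = X @ H @ X.T
    lhs = (lhs + lhs.T) / 2
    rhs = (rhs + rhs.T) / 2 + ridge * np.eye(d)
    try:
        w, V = scipy.linalg.eigh(lhs, rhs)
    except scipy.linalg.LinAlgError:
        warnings.warn("near-singular right-hand side; ridge increased", stacklevel=2)
        rhs += 1e-6 * np.eye(d)
        w, V = scipy.linalg.eigh(lhs, rhs)
    A = _fix_signs(V[:, :p])  # trailing = smallest eigenvalues, ascending
    return A, w[:p]


def ipl_jpda_fit_predict(
    Xs: np.ndarray,
    ys,
    Xt: np.ndarray,
    config: JPDAConfig | None = None,
    y_true=None,
) -> IPLJPDAResult:
    """Run the full adaptation loop and predict target labels.

    ``Xs``/``Xt`` are raw (un-normalized) d x n feature matrices with a
    shared layout; ``ys`` holds 1-based source class codes.  Features are
    z-scored over the pooled columns, iteration 1 assigns improved
    pseudo-labels, and iterations 2..T alternate the eigensolve with
    nearest-neighbour relabeling.  ``y_true`` (optional) fills the
    per-iteration accuracy diagnostic.
    """
    config = config or JPDAConfig()
    Xs = np.asarray(Xs, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    ys = np.asarray(ys, dtype=int)
    ns, nt = Xs.shape[1], Xt.shape[1]
    C = int(config.n_classes or ys.max())

    Xn, _ = normalize(np.hstack([Xs, Xt]))
    Xsn, Xtn = Xn[:, :ns], Xn[:, ns:]

    pl, _ = improved_pseudo_labels(
        Xsn, ys, Xtn, k=config.pca_k, m=config.slpp_m, n_classes=C
    )
    yt = pl.labels
    history = [yt.copy()]
    mmd = [float("nan")]
    Ys1h = one_hot(ys, C)
    A = None
    for _ in range(2, config.T + 1):
        missing = [c for c in range(1, C + 1) if not np.any(yt == c)]
        if missing:
            warnings.warn(
                f"class(es) {missing} absent from current pseudo-labels; "
                "their coupling columns are zero",
                stacklevel=2,
            )
        Yt1h = one_hot(yt, C)
        A, _ = jpda_step(
            Xn, Ys1h, Yt1h, mu=config.mu, lam=config.lam, p=config.p, ridge=config.ridge
        )
        Zs, Zt = A.T @ Xsn, A.T @ Xtn
        clf = KNeighborsClassifier(n_neighbors=config.knn_k)
        clf.fit(Zs.T, ys)
        yt = clf.predict(Zt.T).astype(int)
        history.append(yt.copy())
        Rmin, _ = build_R(Ys1h, Yt1h)
        mmd.append(float(np.trace(A.T @ Xn @ Rmin @ Xn.T @ A)))
    acc = None
    if y_true is not None:
        y_true = np.asarray(y_true, dtype=int)
        acc = [float(np.mean(h == y_true)) for h in history]
    return IPLJPDAResult(
        labels=yt,
        history=history,
        mmd=mmd,
        A=A,
        initial_labels=pl.initial_labels,
        accuracy_history=acc,
    )
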