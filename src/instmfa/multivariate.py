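"""PCA and PLS-DA over Monte Carlo net-flux ensembles.

The two conditions' ensembles are stacked row-wise into a samples x fluxes
matrix restricted to net biochemical fluxes (pool sizes, exchange fluxes and
the pseudo fluxes describing extraction mixing or inactive-pool dilution are
excluded), autoscaled column-wise (mean 0, unit sample variance), and
decomposed to find the fluxes that separate the conditions.  PCA uses the
singular value decomposition; PLS-DA is NIPALS PLS2 on a centred class
indicator, scored by VIP, k-fold cross-validated accuracy, and a label
permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "flux_ensemble_matrix",
    "autoscale",
    "pca",
    "plsda",
    "PCAResult",
    "PLSDAResult",
]


def flux_ensemble_matrix(ens_a, ens_b, labels=("A", "B"), drop_fixed=True):
    """Stack two ensembles' net fluxes into (X, y) for multivariate analysis.

    Pseudo fluxes are excluded; fixed fluxes (e.g. the uptake normalization)
    have zero variance and are dropped here rather than warned about later.
    """
    fa, fb = ens_a.net_flux_frame(), ens_b.net_flux_frame()
    cols = [c for c in fa.columns if c in fb.columns]
    if drop_fixed:
        fixed = set(ens_a._model.param.fixed) | set(ens_b._model.param.fixed)
        cols = [c for c in cols if c not in fixed]
    X = pd.concat([fa[cols], fb[cols]], ignore_index=True)
    y = np.array([labels[0]] * len(fa) + [labels[1]] * len(fb))
    return X, y


def autoscale(X):
    """Mean-centre and scale columns to unit sample (n-1) variance.

    Zero-variance columns carry no information and are dropped with a
    warning.  Returns ``(scaled DataFrame, means, sds)``.
    """
    X = pd.DataFrame(X)
    if X.size == 0:
        raise ValueError("empty matrix")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        warnings.warn(
            f"dropping zero-variance columns: {list(X.columns[~keep])}",
            stacklevel=2)
    Xs = (X.loc[:, keep] - means[keep]) / sds[keep]
    return Xs, means[keep], sds[keep]


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray          # columns are orthonormal components
    explained_variance: np.ndarray
    explained_fraction: np.ndarray
    columns: list


def pca(X, n_components: int = None) -> PCAResult:
    """Principal component analysis by SVD of the (already scaled) matrix.

    Sign convention: the largest-magnitude loading of each component is made
    positive.  ``scores = X @ loadings``; explained fractions sum to <= 1.
    """
    X = pd.DataFrame(X)
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    r = int(np.linalg.matrix_rank(A))
    if n_components is None:
        n_components = min(n - 1, p)
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds the matrix rank bound")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    V = Vt.T[:, :n_components]
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    var = (s[:n_components] ** 2) / (n - 1)
    total = np.sum(A ** 2) / (n - 1)
    return PCAResult(A @ V, V, var, var / total, list(X.columns))


@dataclass
class PLSDAResult:
    scores: np.ndarray            # X scores T
    loadings: np.ndarray          # X loadings P
    weights: np.ndarray           # X weights W
    y_loadings: np.ndarray
    vip: pd.Series
    classes: np.ndarray
    cv_accuracy: float = np.nan
    permutation_accuracies: np.ndarray = None
    permutation_p: float = np.nan


def _nipals_pls2(X, Y, n_components, tol=1e-12, max_iter=500):
    T = np.zeros((X.shape[0], n_components))
    P = np.zeros((X.shape[1], n_components))
    W = np.zeros((X.shape[1], n_components))
    Q = np.zeros((Y.shape[1], n_components))
    Xr, Yr = X.copy(), Y.copy()
    for a in range(n_components):
        u = Yr[:, [np.argmax(np.var(Yr, axis=0))]].copy()
        t_old = None
        for _ in range(max_iter):
            w = Xr.T @ u / (u.T @ u)
            w /= np.linalg.norm(w)
            t = Xr @ w
            q = Yr.T @ t / (t.T @ t)
            u = Yr @ q / (q.T @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        p = Xr.T @ t / (t.T @ t)
        Xr = Xr - t @ p.T
        Yr = Yr - t @ q.T
        T[:, [a]], P[:, [a]], W[:, [a]], Q[:, [a]] = t, p, w, q
    return T, P, W, Q


def _vip(T, W, Q) -> np.ndarray:
    # variable importance in projection; mean square over variables is 1
    p, a = W.shape
    ssy = np.array([(T[:, j] ** 2).sum() * (Q[:, j] ** 2).sum()
                    for j in range(a)])
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (Wn ** 2 @ ssy) / ssy.sum())


def _indicator(y):
    classes = np.unique(y)
    Y = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        Y[y == c, j] = 1.0
    return Y - Y.mean(axis=0), classes


def _predict_class(Xtr, ytr, Xte, n_components):
    Ytr, classes = _indicator(ytr)
    T, P, W, Q = _nipals_pls2(Xtr, Ytr, n_components)
    B = W @ np.linalg.pinv(P.T @ W) @ Q.T
    raw = np.zeros((len(ytr), len(classes)))
    for j, c in enumerate(classes):
        raw[ytr == c, j] = 1.0
    pred = Xte @ B + raw.mean(axis=0)
    return classes[np.argmax(pred, axis=1)]


def plsda(X, y, n_components: int = 2, cv_folds: int = 5,
          n_permutations: int = 0, seed=None) -> PLSDAResult:
    """PLS discriminant analysis on an autoscaled matrix and 2-class labels.

    Components maximize covariance with the centred class indicator; VIP
    scores rank each flux's contribution.  Optional k-fold cross-validated
    accuracy and a label-permutation null check that the separation is real.
    """
    X = pd.DataFrame(X)
    A = X.to_numpy(dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("PLS-DA here requires exactly 2 classes")
    Y, classes = _indicator(y)
    n_components = min(n_components, A.shape[1], A.shape[0] - 1)
    T, P, W, Q = _nipals_pls2(A, Y, n_components)
    vip = pd.Series(_vip(T, W, Q), index=X.columns).sort_values(ascending=False)
    res = PLSDAResult(T, P, W, Q, vip, classes)

    rng = np.random.default_rng(seed)

    def cv_accuracy(labels):
        idx = rng.permutation(len(labels))
        folds = np.array_split(idx, cv_folds)
        hits = 0
        for f in folds:
            mask = np.ones(len(labels), bool)
            mask[f] = False
            if len(np.unique(labels[mask])) < 2:
                continue
            pred = _predict_class(A[mask], labels[mask], A[f], n_components)
            hits += int(np.sum(pred == labels[f]))
        return hits / len(labels)

    if cv_folds and cv_folds > 1:
        res.cv_accuracy = cv_accuracy(y)
    if n_permutations:
        perms = np.array([cv_accuracy(rng.permutation(y))
                          for _ in range(n_permutations)])
        res.permutation_accuracies = perms
        res.permutation_p = float(
            (np.sum(perms >= res.cv_accuracy) + 1) / (n_permutations + 1))
    return res
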