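"""Univariate-response partial least squares (PLS1) via NIPALS.

This is the workhorse behind both the calibration models and the variable
selectors.  The selectors evaluate on the order of 10^5 cross-validated PLS
sub-models per run, so the core fit and the fold loop are compiled with
numba; one NIPALS pass returns the weights/loadings for all component
counts up to ``a_max``, which makes per-fold component selection essentially
free.

Conventions: X and y are column-centered inside each training fold; no
variance scaling is applied (the pipeline's preprocessors own scaling).
Component extraction stops early when the residual covariance vanishes, so
requesting more components than the data supports is safe.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "make_folds",
    "fit_pls1",
    "cv_rmse_components",
    "choose_components",
    "bms_cv_rmse",
    "loo_pls_coefs",
    "PLS1Model",
]

_EPS = 1e-12


@njit(cache=True)
def _nipals(Xc, yc, a_max):
    """NIPALS PLS1 on centered data; returns (W, P, q, a_eff)."""
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    a_eff = 0
    for a in range(a_max):
        w = X.T @ y
        wn = np.sqrt(np.sum(w * w))
        if wn < _EPS:
            break
        w = w / wn
        t = X @ w
        tt = np.sum(t * t)
        if tt < _EPS:
            break
        pv = (X.T @ t) / tt
        qa = np.dot(y, t) / tt
        X = X - np.outer(t, pv)
        y = y - qa * t
        W[:, a] = w
        P[:, a] = pv
        q[a] = qa
        a_eff = a + 1
    return W, P, q, a_eff


@njit(cache=True)
def _coefs_all(W, P, q, a_eff):
    """Regression vectors for every component count 1..a_eff (p x a_eff)."""
    p = W.shape[0]
    B = np.zeros((p, a_eff))
    for a in range(1, a_eff + 1):
        M = P[:, :a].T @ W[:, :a]
        sol = np.linalg.solve(M, q[:a].copy())
        B[:, a - 1] = W[:, :a] @ sol
    return B


@njit(cache=True)
def cv_rmse_components(X, y, fold_id, n_folds, a_max):
    """Pooled out-of-fold RMSE for each component count 1..a_max.

    Entries beyond the number of extractable components repeat the last
    attainable value, so ``argmin`` picks the smallest sufficient count.
    """
    n, p = X.shape
    sse = np.zeros(a_max)
    for f in range(n_folds):
        n_te = 0
        for i in range(n):
            if fold_id[i] == f:
                n_te += 1
        n_tr = n - n_te
        if n_te == 0:
            continue
        Xtr = np.empty((n_tr, p))
        ytr = np.empty(n_tr)
        Xte = np.empty((n_te, p))
        yte = np.empty(n_te)
        it = 0
        ie = 0
        for i in range(n):
            if fold_id[i] == f:
                Xte[ie] = X[i]
                yte[ie] = y[i]
                ie += 1
            else:
                Xtr[it] = X[i]
                ytr[it] = y[i]
                it += 1
        xm = np.zeros(p)
        for j in range(p):
            xm[j] = Xtr[:, j].mean()
        ym = ytr.mean()
        cap = min(a_max, p, n_tr - 1)
        if cap < 1:
            cap = 1
        W, P, q, a_eff = _nipals(Xtr - xm, ytr - ym, cap)
        if a_eff == 0:
            # degenerate: mean-only prediction for all counts
            for a in range(a_max):
                for i in range(n_te):
                    d = yte[i] - ym
                    sse[a] += d * d
            continue
        B = _coefs_all(W, P, q, a_eff)
        preds = (Xte - xm) @ B + ym
        for a in range(a_max):
            col = min(a, a_eff - 1)
            for i in range(n_te):
                d = preds[i, col] - yte[i]
                sse[a] += d * d
    return np.sqrt(sse / n)


@njit(cache=True)
def bms_cv_rmse(X, y, incl, fold_id, n_folds, a_max):
    """Min-over-components CV RMSE for each row of a binary inclusion matrix."""
    n_rows = incl.shape[0]
    n = X.shape[0]
    out = np.empty(n_rows)
    for r in range(n_rows):
        m = 0
        for j in range(incl.shape[1]):
            if incl[r, j]:
                m += 1
        Xs = np.empty((n, m))
        c = 0
        for j in range(incl.shape[1]):
            if incl[r, j]:
                Xs[:, c] = X[:, j]
                c += 1
        rmse = cv_rmse_components(Xs, y, fold_id, n_folds, min(a_max, m))
        out[r] = rmse.min()
    return out


@njit(cache=True)
def loo_pls_coefs(X, y, a_max):
    """Leave-one-out refits: row i holds the regression vector of the model
    fitted without sample i, at the largest attainable component count
    <= a_max."""
    n, p = X.shape
    B = np.zeros((n, p))
    Xtr = np.empty((n - 1, p))
    ytr = np.empty(n - 1)
    for i in range(n):
        c = 0
        for k in range(n):
            if k != i:
                Xtr[c] = X[k]
                ytr[c] = y[k]
                c += 1
        xm = np.zeros(p)
        for j in range(p):
            xm[j] = Xtr[:, j].mean()
        ym = ytr.mean()
        cap = min(a_max, p, n - 2)
        if cap < 1:
            cap = 1
        W, P, q, a_eff = _nipals(Xtr - xm, ytr - ym, cap)
        if a_eff > 0:
            Ball = _coefs_all(W, P, q, a_eff)
            B[i] = Ball[:, a_eff - 1]
    return B


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded shuffled fold assignment (balanced sizes)."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n < n_folds:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=np.int64)
    fold_id[perm] = np.arange(n) % n_folds
    return fold_id


class PLS1Model:
    """Fitted PLS1 regression: ``predict(X) = (X - x_mean) @ coef + y_mean``."""

    def __init__(self, x_mean, y_mean, coef, n_components, rmsecv_curve=None):
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.y_mean = float(y_mean)
        self.coef = np.asarray(coef, dtype=float)
        self.n_components = int(n_components)
        self.rmsecv_curve = rmsecv_curve

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.y_mean


def fit_pls1(X, y, n_components: int) -> PLS1Model:
    """Fit PLS1 with a fixed component count (capped at the data's rank)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    cap = min(n_components, p, n - 1)
    if cap < 1:
        raise ValueError("cannot extract any latent variable")
    xm = X.mean(axis=0)
    ym = y.mean()
    W, P, q, a_eff = _nipals(X - xm, y - ym, cap)
    if a_eff == 0:
        raise ValueError("no latent variable could be extracted")
    B = _coefs_all(W, P, q, a_eff)
    return PLS1Model(xm, ym, B[:, a_eff - 1], a_eff)


def choose_components(X, y, a_max: int, n_folds: int, seed: int):
    """Pick the component count minimising pooled CV RMSE.

    Returns ``(best_a, rmse_at_best, rmse_curve)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    fold_id = make_folds(len(y), n_folds, seed)
    cap = max(1, min(a_max, X.shape[1]))
    curve = cv_rmse_components(X, y, fold_id, n_folds, cap)
    # parsimony: smallest count within numerical tolerance of the minimum
    lo = float(curve.min())
    best = int(np.argmax(curve <= lo * (1.0 + 1e-8) + 1e-12))
    return best + 1, float(curve[best]), curve
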