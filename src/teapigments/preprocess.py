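"""Preprocessing operators and Kennard-Stone sample-set partitioning.

Three row/column operators are offered, mirroring common chemometric
practice on spectrum-like feature rows:

* **MSC** (multiplicative scatter correction): each row ``x`` is regressed on
  the calibration mean row ``m`` as ``x = a + b*m``; the corrected row is
  ``(x - a) / b``.  By default the whole 210-cell row is treated as one
  spectrum; per-parameter-block correction is available via
  ``msc_per_block=True``.
* **Min-Max**: per-column scaling to [0, 1] using bounds learned on the
  calibration set (prediction rows may fall outside [0, 1]).
* **Smooth**: centered moving average along the frequency axis, applied
  separately within each parameter block so physically different parameters
  are never mixed across the concatenation boundary; edges use shrinking
  windows.

All statistics are learned on calibration data only; ``apply`` never updates
state.  The Kennard-Stone splitter is the classic deterministic max-min
procedure, with Mahalanobis distance (ridge-regularised covariance, needed
when p > n) or plain Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PreprocessSpec",
    "fit_preprocessor",
    "apply_preprocessor",
    "SplitResult",
    "kennard_stone_split",
]

_METHODS = ("none", "msc", "minmax", "smooth")


@dataclass
class PreprocessSpec:
    """Preprocessing method plus (after fitting) its learned statistics."""

    method: str = "none"
    smooth_window: int = 5
    block_size: int | None = 30  # frequency-block length for Smooth / per-block MSC
    msc_per_block: bool = False
    # learned state
    mean_spectrum_: np.ndarray | None = field(default=None, repr=False)
    col_min_: np.ndarray | None = field(default=None, repr=False)
    col_max_: np.ndarray | None = field(default=None, repr=False)
    n_columns_: int | None = None

    def __post_init__(self) -> None:
        method = self.method.lower()
        if method == "min-max":
            method = "minmax"
        if method not in _METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        self.method = method
        if self.method == "smooth":
            if self.smooth_window < 3 or self.smooth_window % 2 == 0:
                raise ValueError("smooth_window must be odd and >= 3")

    @property
    def is_fitted(self) -> bool:
        if self.method == "msc":
            return self.mean_spectrum_ is not None
        if self.method == "minmax":
            return self.col_min_ is not None
        return self.n_columns_ is not None


def fit_preprocessor(X_cal: np.ndarray, spec: PreprocessSpec) -> PreprocessSpec:
    """Learn calibration statistics; returns a new fitted spec."""
    X = np.asarray(X_cal, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X_cal must be a non-empty 2-D matrix")
    fitted = PreprocessSpec(
        method=spec.method,
        smooth_window=spec.smooth_window,
        block_size=spec.block_size,
        msc_per_block=spec.msc_per_block,
    )
    fitted.n_columns_ = X.shape[1]
    if spec.method == "msc":
        fitted.mean_spectrum_ = X.mean(axis=0)
    elif spec.method == "minmax":
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        constant = np.flatnonzero(hi - lo == 0)
        if constant.size:
            raise ValueError(
                f"Min-Max cannot scale constant column {int(constant[0])}"
            )
        fitted.col_min_ = lo
        fitted.col_max_ = hi
    return fitted


def _msc_rows(X: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Per-row affine regression on reference spectrum m, then inversion."""
    mc = m - m.mean()
    denom = float(mc @ mc)
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ mc / denom
    bad = np.flatnonzero(b <= 0)
    if bad.size:
        raise ValueError(f"MSC slope <= 0 for row {int(bad[0])}")
    a = X.mean(axis=1) - b * m.mean()
    return (X - a[:, None]) / b[:, None]


def _smooth_block(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along columns with shrinking edge windows."""
    n_cols = X.shape[1]
    half = window // 2
    out = np.empty_like(X)
    csum = np.cumsum(X, axis=1)
    for j in range(n_cols):
        lo = max(0, j - half)
        hi = min(n_cols, j + half + 1)
        total = csum[:, hi - 1] - (csum[:, lo - 1] if lo > 0 else 0.0)
        out[:, j] = total / (hi - lo)
    return out


def apply_preprocessor(X: np.ndarray, fitted: PreprocessSpec) -> np.ndarray:
    """Transform rows using calibration-learned statistics only."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not fitted.is_fitted:
        raise ValueError("preprocessor has not been fitted")
    if fitted.n_columns_ is not None and X.shape[1] != fitted.n_columns_:
        raise ValueError(
            f"column count {X.shape[1]} does not match fit ({fitted.n_columns_})"
        )
    if fitted.method == "none":
        return X.copy()
    if fitted.method == "msc":
        m = fitted.mean_spectrum_
        if not fitted.msc_per_block:
            return _msc_rows(X, m)
        out = np.empty_like(X)
        for lo, hi in _blocks(X.shape[1], fitted.block_size):
            out[:, lo:hi] = _msc_rows(X[:, lo:hi], m[lo:hi])
        return out
    if fitted.method == "minmax":
        return (X - fitted.col_min_) / (fitted.col_max_ - fitted.col_min_)
    # smooth
    out = np.empty_like(X)
    for lo, hi in _blocks(X.shape[1], fitted.block_size):
        out[:, lo:hi] = _smooth_block(X[:, lo:hi], fitted.smooth_window)
    return out


def _blocks(n_cols: int, block_size: int | None):
    if block_size is None or block_size >= n_cols:
        return [(0, n_cols)]
    if n_cols % block_size != 0:
        raise ValueError(
            f"{n_cols} columns do not divide into blocks of {block_size}"
        )
    return [(i, i + block_size) for i in range(0, n_cols, block_size)]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/prediction sample-index partition."""

    calibration_indices: tuple[int, ...]
    prediction_indices: tuple[int, ...]
    metric: str

    def __post_init__(self) -> None:
        cal = set(self.calibration_indices)
        pred = set(self.prediction_indices)
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")


def _mahalanobis_coords(X: np.ndarray) -> np.ndarray:
    """Whitening transform so Euclidean distance equals Mahalanobis distance.

    The covariance is estimated on all rows; a ridge of 1e-6 x mean diagonal
    is added when the matrix is singular (certain when p >= n).
    """
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * np.mean(np.diag(cov))
        if ridge <= 0:
            ridge = 1e-12
        L = np.linalg.cholesky(cov + ridge * np.eye(cov.shape[0]))
    from scipy.linalg import solve_triangular

    return solve_triangular(L, Xc.T, lower=True).T


def kennard_stone_split(
    X: np.ndarray,
    calibration_fraction: float,
    metric: str = "mahalanobis",
) -> SplitResult:
    """Classic Kennard-Stone max-min selection of a calibration subset.

    Seeds with the two mutually farthest samples, then repeatedly adds the
    sample whose minimum distance to the chosen set is largest, until the
    calibration count ``n - floor(n * (1 - fraction))`` is reached.  Ties are
    broken toward the lower index, making the procedure fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (0.0 < calibration_fraction < 1.0):
        raise ValueError("calibration_fraction must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_pred = int(np.floor(n * (1.0 - calibration_fraction)))
    n_cal = n - n_pred
    if n_cal < 2 or n_pred < 1:
        raise ValueError("fraction yields an empty or degenerate side")
    if metric == "mahalanobis":
        coords = _mahalanobis_coords(X)
    elif metric == "euclidean":
        coords = X
    else:
        raise ValueError(f"unknown metric {metric!r}")

    D = squareform(pdist(coords))
    # seed: the mutually farthest pair (lowest indices on ties)
    flat = np.argmax(D)
    i, j = np.unravel_index(flat, D.shape)
    selected = [min(i, j), max(i, j)]
    chosen = np.zeros(n, dtype=bool)
    chosen[selected] = True
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[chosen] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        chosen[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[chosen] = -np.inf
    cal = tuple(sorted(int(k) for k in selected))
    pred = tuple(int(k) for k in range(n) if not chosen[k])
    return SplitResult(cal, pred, metric)
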