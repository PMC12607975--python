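"""Calibration models, evaluation metrics and the end-to-end pipeline.

Two regressors are offered: PLSR (NIPALS latent variables, component count
chosen by cross-validated RMSE up to a ceiling) and epsilon-insensitive SVR
with an RBF kernel, whose penalty ``c`` and kernel width ``g`` are tuned by a
coarse power-of-two grid search plus one refinement pass around the winning
pair.  Models are compared with the standard chemometric diagnostics:

* ``R_cv`` / ``RMSECV`` -- Pearson correlation and RMSE of pooled
  out-of-fold predictions on the calibration set (10-fold by default);
* ``R_p`` / ``RMSEP`` -- the same on the untouched prediction set;
* ``RPD`` -- sd(prediction-set reference, n-1 denominator) / RMSEP; values
  above 2 are conventionally read as satisfactory, above ~6.5 as excellent.

``run_pipeline`` wires everything together: Kennard-Stone split, leakage-free
preprocessing (fit on calibration only), optional variable selection on the
calibration side, model fitting, cross-validation and prediction-set
evaluation, one :class:`EvalReport` per (pigment, preprocess, selector,
model) combination.  A single master seed makes the whole table reproducible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.svm import SVR as _SkSVR

from .core_data import ElectricalDataset, PigmentRecord, pigment_vector
from .pls import PLS1Model, choose_components, fit_pls1, make_folds
from .preprocess import (
    PreprocessSpec,
    SplitResult,
    apply_preprocessor,
    fit_preprocessor,
    kennard_stone_split,
)
from .varselect import SelectionResult, SelectorConfig, select

__all__ = [
    "PLSRConfig",
    "SVRConfig",
    "EvalReport",
    "PipelineSpec",
    "DEFAULT_COMBOS",
    "plsr_fit",
    "svr_fit",
    "cross_validate",
    "evaluate_on_prediction",
    "run_pipeline",
    "render_report",
]

log = logging.getLogger("teapigments")


@dataclass(frozen=True)
class PLSRConfig:
    max_components: int = 10
    cv_folds: int = 10
    component_rule: str = "min_rmsecv"


def _pow2_grid(lo: int = -8, hi: int = 8) -> tuple[float, ...]:
    return tuple(float(2.0**e) for e in range(lo, hi + 1))


@dataclass(frozen=True)
class SVRConfig:
    kernel: str = "RBF"
    c_grid: tuple[float, ...] = field(default_factory=_pow2_grid)
    g_grid: tuple[float, ...] = field(default_factory=_pow2_grid)
    epsilon: float = 0.01
    cv_folds: int = 10
    refine: bool = True

    def __post_init__(self) -> None:
        if self.kernel != "RBF":
            raise ValueError("only the RBF kernel is supported")
        if not self.c_grid or not self.g_grid:
            raise ValueError("grids must be non-empty")
        if min(self.c_grid) <= 0 or min(self.g_grid) <= 0:
            raise ValueError("grid values must be positive")


@dataclass
class EvalReport:
    """One row of the model-comparison table."""

    quality_index: str  # TF | TR | TB
    model: str  # PLSR | SVR
    selector: str  # none | CARS | UVE | VCPA_IRIV
    preprocess: str
    n_variables: int
    pcs_or_params: str  # latent-variable count, or "c=..., g=..."
    R_cv: float
    RMSECV: float
    R_p: float
    RMSEP: float
    RPD: float

    def __post_init__(self) -> None:
        if self.RMSECV < 0 or self.RMSEP < 0:
            raise ValueError("RMSE metrics must be non-negative")

    def to_row(self) -> dict:
        return {
            "pigment": self.quality_index,
            "preprocess": self.preprocess,
            "selector": self.selector,
            "model": self.model,
            "n_variables": self.n_variables,
            "pcs_or_params": self.pcs_or_params,
            "R_cv": self.R_cv,
            "RMSECV": self.RMSECV,
            "R_p": self.R_p,
            "RMSEP": self.RMSEP,
            "RPD": self.RPD,
        }


class PLSRModel:
    """PLSR with CV-chosen latent-variable count."""

    def __init__(self, core: PLS1Model, n_components: int, rmsecv_curve):
        self._core = core
        self.n_components = n_components
        self.rmsecv_curve = rmsecv_curve

    @property
    def coef(self) -> np.ndarray:
        return self._core.coef

    def predict(self, X) -> np.ndarray:
        return self._core.predict(X)


def plsr_fit(X_cal, y_cal, config: PLSRConfig = PLSRConfig(),
             seed: int = 0) -> PLSRModel:
    """Fit PLSR, choosing the component count by cv_folds-fold RMSECV."""
    X = np.ascontiguousarray(X_cal, dtype=float)
    y = np.ascontiguousarray(y_cal, dtype=float)
    n, p = X.shape
    if n < config.cv_folds:
        raise ValueError("fewer samples than CV folds")
    a_max = min(config.max_components, p, n - 1)
    if a_max < config.max_components:
        warnings.warn(
            f"max_components truncated from {config.max_components} to "
            f"{a_max} (rank limit)", UserWarning, stacklevel=2,
        )
    best_a, _, curve = choose_components(X, y, a_max, config.cv_folds, seed)
    core = fit_pls1(X, y, best_a)
    return PLSRModel(core, core.n_components, curve)


class SVRModel:
    """RBF SVR on internally z-scored features, with tuned (c, g)."""

    def __init__(self, svr, x_mean, x_sd, c, g, epsilon, cv_rmse):
        self._svr = svr
        self.x_mean = x_mean
        self.x_sd = x_sd
        self.c = c
        self.g = g
        self.epsilon = epsilon
        self.cv_rmse = cv_rmse

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._svr.predict((X - self.x_mean) / self.x_sd)


def _svr_cv_rmse(Xs, y, c, g, epsilon, fold_id, n_folds) -> float:
    sse = 0.0
    for f in range(n_folds):
        te = fold_id == f
        svr = _SkSVR(kernel="rbf", C=c, gamma=g, epsilon=epsilon)
        svr.fit(Xs[~te], y[~te])
        resid = svr.predict(Xs[te]) - y[te]
        sse += float(resid @ resid)
    return math.sqrt(sse / len(y))


def svr_fit(X_cal, y_cal, config: SVRConfig = SVRConfig(),
            seed: int = 0) -> SVRModel:
    """Grid-searched RBF SVR; a refinement pass narrows in on the coarse
    winner with quarter-exponent steps."""
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float)
    n = len(y)
    if n < config.cv_folds:
        raise ValueError("fewer samples than CV folds")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    x_sd = np.where(x_sd < 1e-12, 1.0, x_sd)
    Xs = (X - x_mean) / x_sd
    if not np.isfinite(Xs).all():
        raise ValueError("non-finite values after standardisation")
    fold_id = make_folds(n, config.cv_folds, seed)

    def search(pairs):
        best = None
        for c, g in pairs:
            rmse = _svr_cv_rmse(Xs, y, c, g, config.epsilon, fold_id,
                                config.cv_folds)
            if best is None or rmse < best[0]:
                best = (rmse, c, g)
        return best

    coarse = [(c, g) for c in config.c_grid for g in config.g_grid]
    best = search(coarse)
    if config.refine:
        bc, bg = math.log2(best[1]), math.log2(best[2])
        fine = [
            (2.0 ** (bc + dc), 2.0 ** (bg + dg))
            for dc in np.arange(-1.0, 1.01, 0.25)
            for dg in np.arange(-1.0, 1.01, 0.25)
        ]
        best = min(best, search(fine), key=lambda t: t[0])
    rmse, c, g = best
    svr = _SkSVR(kernel="rbf", C=c, gamma=g, epsilon=config.epsilon)
    svr.fit(Xs, y)
    return SVRModel(svr, x_mean, x_sd, c, g, config.epsilon, rmse)


def cross_validate(fit_fn: Callable, X, y, folds: int = 10,
                   seed: int = 0) -> tuple[float, float]:
    """Seeded k-fold CV with pooled out-of-fold predictions.

    ``fit_fn(X_train, y_train)`` must return an object with ``predict``.
    Returns ``(R_cv, RMSECV)``; a constant out-of-fold prediction vector has
    undefined correlation and is reported as R_cv = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    fold_id = make_folds(n, folds, seed)
    for f in range(folds):
        if (fold_id != f).sum() < 2:
            raise ValueError(f"fold {f} leaves fewer than 2 training samples")
    oof = np.empty(n)
    for f in range(folds):
        te = fold_id == f
        model = fit_fn(X[~te], y[~te])
        oof[te] = model.predict(X[te])
    rmsecv = float(np.sqrt(np.mean((oof - y) ** 2)))
    r_cv = _safe_pearson(y, oof)
    return r_cv, rmsecv


def _safe_pearson(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        log.warning("constant vector in correlation; reporting R = 0")
        return 0.0
    return float(pearsonr(a, b)[0])


def evaluate_on_prediction(model, X_pred, y_pred_ref) -> tuple[float, float, float]:
    """Prediction-set diagnostics ``(R_p, RMSEP, RPD)``.

    RPD uses the (n-1)-denominator standard deviation of the reference
    values; a zero RMSEP yields an infinite RPD sentinel.
    """
    X = np.asarray(X_pred, dtype=float)
    y = np.asarray(y_pred_ref, dtype=float)
    if len(y) < 3:
        raise ValueError("prediction set needs at least 3 samples")
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("prediction-set reference has zero variance")
    pred = model.predict(X)
    rmsep = float(np.sqrt(np.mean((pred - y) ** 2)))
    r_p = _safe_pearson(y, pred)
    rpd = math.inf if rmsep == 0 else sd / rmsep
    return r_p, rmsep, rpd


# ---------------------------------------------------------------------------
# end-to-end pipeline

#: The headline comparison grid: four preprocessors with full-variable PLSR,
#: the three selectors on smoothed data with PLSR, and the hybrid selector
#: with SVR.
DEFAULT_COMBOS: tuple[tuple[str, str, str], ...] = (
    ("none", "none", "PLSR"),
    ("msc", "none", "PLSR"),
    ("minmax", "none", "PLSR"),
    ("smooth", "none", "PLSR"),
    ("smooth", "CARS", "PLSR"),
    ("smooth", "UVE", "PLSR"),
    ("smooth", "VCPA_IRIV", "PLSR"),
    ("smooth", "VCPA_IRIV", "SVR"),
)


@dataclass
class PipelineSpec:
    """What to run: combination grid, split settings, model settings, seed."""

    combos: tuple[tuple[str, str, str], ...] = DEFAULT_COMBOS
    pigments: tuple[str, ...] = ("TF", "TR", "TB")
    split_fraction: float = 2.0 / 3.0
    split_metric: str = "mahalanobis"
    smooth_window: int = 5
    block_size: int | None = 30
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    plsr: PLSRConfig = field(default_factory=PLSRConfig)
    svr: SVRConfig = field(default_factory=SVRConfig)
    seed: int = 0


def _selector_seed(master: int, pigment: str, algorithm: str) -> int:
    pig_rank = ("TF", "TR", "TB").index(pigment)
    alg_rank = ("CARS", "UVE", "VCPA_IRIV").index(algorithm)
    return (master * 97 + pig_rank * 13 + alg_rank * 3 + 1) % (2**31 - 1)


def run_pipeline(
    ds: ElectricalDataset,
    reference: Sequence[PigmentRecord],
    spec: PipelineSpec | None = None,
) -> tuple[list[EvalReport], dict]:
    """Execute the full protocol; returns reports plus an artifact dict
    (split, per-combination selections) for persistence/replay.

    A failing combination is logged and skipped; it never aborts the run.
    """
    spec = spec or PipelineSpec()
    X_raw = ds.matrix
    split = kennard_stone_split(X_raw, spec.split_fraction, spec.split_metric)
    cal = np.array(split.calibration_indices)
    pred = np.array(split.prediction_indices)
    fold_seed = (spec.seed * 31 + 7) % (2**31 - 1)

    prep_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sel_cache: dict[tuple[str, str, str], SelectionResult] = {}
    reports: list[EvalReport] = []
    artifacts: dict = {"split": split, "selections": sel_cache}

    for pigment in spec.pigments:
        y = pigment_vector(reference, pigment)
        y_cal, y_pred = y[cal], y[pred]
        for prep_name, sel_name, model_name in spec.combos:
            try:
                if prep_name not in prep_cache:
                    prep = fit_preprocessor(
                        X_raw[cal],
                        PreprocessSpec(method=prep_name,
                                       smooth_window=spec.smooth_window,
                                       block_size=spec.block_size),
                    )
                    prep_cache[prep_name] = (
                        apply_preprocessor(X_raw[cal], prep),
                        apply_preprocessor(X_raw[pred], prep),
                    )
                Xc_cal, Xc_pred = prep_cache[prep_name]

                if sel_name != "none":
                    key = (pigment, prep_name, sel_name)
                    if key not in sel_cache:
                        cfg = SelectorConfig(
                            algorithm=sel_name,
                            cars_runs=spec.selector.cars_runs,
                            cars_folds=spec.selector.cars_folds,
                            cars_row_fraction=spec.selector.cars_row_fraction,
                            uve_components=spec.selector.uve_components,
                            uve_threshold=spec.selector.uve_threshold,
                            uve_cutoff_rule=spec.selector.uve_cutoff_rule,
                            vcpa_edf_target=spec.selector.vcpa_edf_target,
                            vcpa_bms_runs=spec.selector.vcpa_bms_runs,
                            vcpa_iterations=spec.selector.vcpa_iterations,
                            vcpa_folds=spec.selector.vcpa_folds,
                            vcpa_best_fraction=spec.selector.vcpa_best_fraction,
                            iriv_alpha=spec.selector.iriv_alpha,
                            max_pls_components=spec.selector.max_pls_components,
                            seed=_selector_seed(spec.seed, pigment, sel_name),
                        )
                        sel_cache[key] = select(Xc_cal, y_cal, cfg)
                    chosen = sel_cache[key].selected
                    Xm_cal = Xc_cal[:, chosen]
                    Xm_pred = Xc_pred[:, chosen]
                else:
                    Xm_cal, Xm_pred = Xc_cal, Xc_pred

                if model_name == "PLSR":
                    model = plsr_fit(Xm_cal, y_cal, spec.plsr, seed=fold_seed)
                    a = model.n_components

                    def refit(Xtr, ytr, _a=a):
                        return fit_pls1(Xtr, ytr, _a)

                    r_cv, rmsecv = cross_validate(refit, Xm_cal, y_cal,
                                                  spec.plsr.cv_folds, fold_seed)
                    params = str(model.n_components)
                elif model_name == "SVR":
                    model = svr_fit(Xm_cal, y_cal, spec.svr, seed=fold_seed)

                    def refit(Xtr, ytr, _m=model):
                        svr = _SkSVR(kernel="rbf", C=_m.c, gamma=_m.g,
                                     epsilon=_m.epsilon)
                        xm = Xtr.mean(axis=0)
                        sd = np.where(Xtr.std(axis=0) < 1e-12, 1.0,
                                      Xtr.std(axis=0))
                        svr.fit((Xtr - xm) / sd, ytr)

                        class _P:
                            def predict(self, Xte, _svr=svr, _xm=xm, _sd=sd):
                                return _svr.predict((Xte - _xm) / _sd)

                        return _P()

                    r_cv, rmsecv = cross_validate(refit, Xm_cal, y_cal,
                                                  spec.svr.cv_folds, fold_seed)
                    params = f"c={model.c:.4g}, g={model.g:.4g}"
                else:
                    raise ValueError(f"unknown model {model_name!r}")

                r_p, rmsep, rpd = evaluate_on_prediction(model, Xm_pred, y_pred)
                reports.append(EvalReport(
                    quality_index=pigment,
                    model=model_name,
                    selector=sel_name,
                    preprocess=prep_name,
                    n_variables=Xm_cal.shape[1],
                    pcs_or_params=params,
                    R_cv=r_cv,
                    RMSECV=rmsecv,
                    R_p=r_p,
                    RMSEP=rmsep,
                    RPD=rpd,
                ))
            except Exception:
                log.exception(
                    "combination (%s, %s, %s, %s) failed; skipping",
                    pigment, prep_name, sel_name, model_name,
                )
    return reports, artifacts


def reports_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


def render_report(reports: Sequence[EvalReport], out_dir) -> dict[str, Path]:
    """Persist the comparison table (CSV, sorted by RPD within pigment) and a
    bubble chart (x = R_p, y = RPD, radius ~ RMSEP, label = n_variables)."""
    if not reports:
        raise ValueError("no reports to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = reports_frame(reports)
    df = df.sort_values(["pigment", "RPD"], ascending=[True, False],
                        kind="stable").reset_index(drop=True)
    csv_path = out / "model_comparison.csv"
    df.to_csv(csv_path, index=False, float_format="%.6f")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"TF": "tab:red", "TR": "tab:green", "TB": "tab:blue"}
    fig, ax = plt.subplots(figsize=(7, 5))
    finite = df[np.isfinite(df["RPD"])]
    max_rmsep = finite["RMSEP"].max() or 1.0
    for _, row in finite.iterrows():
        ax.scatter(row["R_p"], row["RPD"],
                   s=200 + 1800 * row["RMSEP"] / max_rmsep,
                   alpha=0.5, color=colors.get(row["pigment"], "gray"))
        ax.annotate(str(int(row["n_variables"])), (row["R_p"], row["RPD"]),
                    ha="center", va="center", fontsize=8)
    ax.set_xlabel("$R_p$")
    ax.set_ylabel("RPD")
    ax.set_title("Model comparison (bubble radius ~ RMSEP, label = #variables)")
    handles = [plt.Line2D([], [], marker="o", ls="", color=c, label=k)
               for k, c in colors.items() if k in set(finite["pigment"])]
    ax.legend(handles=handles, title="pigment")
    chart_path = out / "model_comparison.png"
    fig.tight_layout()
    fig.savefig(chart_path, dpi=120)
    plt.close(fig)
    return {"csv": csv_path, "chart": chart_path}
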