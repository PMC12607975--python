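import math

import numpy as np
import pandas as pd
import pytest

from teapigments.calibrate import (
    DEFAULT_COMBOS,
    EvalReport,
    PipelineSpec,
    PLSRConfig,
    SVRConfig,
    cross_validate,
    evaluate_on_prediction,
    plsr_fit,
    render_report,
    reports_frame,
    run_pipeline,
    svr_fit,
)
from teapigments.pls import fit_pls1, make_folds
from teapigments.preprocess import PreprocessSpec, apply_preprocessor, fit_preprocessor
from teapigments.synthetic import SimConfig, simulate
from teapigments.varselect import SelectorConfig, select


class _Identity:
    """Predictor returning its input's first column (X carries y)."""

    def predict(self, X):
        return np.asarray(X)[:, 0]


class TestCrossValidate:
    def test_perfect_model(self, rng):
        y = rng.normal(size=20)
        X = y[:, None]
        r, rmse = cross_validate(lambda X_, y_: _Identity(), X, y, folds=5, seed=0)
        assert r == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_flagged(self, rng):
        y = rng.normal(size=20)
        X = rng.normal(size=(20, 3))

        class _Const:
            def __init__(self, c):
                self.c = c

            def predict(self, X_):
                return np.full(len(X_), self.c)

        r, rmse = cross_validate(lambda Xt, yt: _Const(y.mean()), X, y,
                                 folds=4, seed=1)
        assert r == 0.0  # undefined correlation reported as 0 with a flag
        assert rmse == pytest.approx(np.std(y), rel=1e-6)

    def test_two_fold_hand_computed_linear_model(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 1.0, 2.0, 10.0])

        def fit_line(Xt, yt):
            slope, icpt = np.polyfit(Xt[:, 0], yt, 1)

            class _L:
                def predict(self, X_):
                    return slope * X_[:, 0] + icpt

            return _L()

        fold_id = make_folds(4, 2, 3)
        oof = np.empty(4)
        for f in range(2):
            te = fold_id == f
            oof[te] = fit_line(X[~te], y[~te]).predict(X[te])
        expected_rmse = np.sqrt(np.mean((oof - y) ** 2))
        r, rmse = cross_validate(fit_line, X, y, folds=2, seed=3)
        assert rmse == pytest.approx(expected_rmse)

    def test_degenerate_fold_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(lambda X, y: _Identity(), np.ones((3, 1)),
                           np.arange(3.0), folds=4, seed=0)
        # 2 samples / 2 folds leaves single-sample training folds
        with pytest.raises(ValueError):
            cross_validate(lambda X, y: _Identity(), np.ones((2, 1)),
                           np.arange(2.0), folds=2, seed=0)


class TestEvaluate:
    def test_exact_predictions_give_infinite_rpd(self):
        y = np.array([1.0, 2.0, 3.0])
        r, rmsep, rpd = evaluate_on_prediction(_Identity(), y[:, None], y)
        assert rmsep == 0.0 and math.isinf(rpd) and r == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        y = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.0, 2.0, 4.0])
        r, rmsep, rpd = evaluate_on_prediction(_Identity(), pred[:, None], y)
        assert rmsep == pytest.approx(np.sqrt(1.0 / 3.0))
        assert rpd == pytest.approx(np.sqrt(3.0))

    def test_scale_equivariance(self, rng):
        y = rng.normal(size=10)
        pred = y + rng.normal(0, 0.1, 10)
        r1, rmsep1, rpd1 = evaluate_on_prediction(_Identity(), pred[:, None], y)
        r2, rmsep2, rpd2 = evaluate_on_prediction(_Identity(),
                                                  (10 * pred)[:, None], 10 * y)
        assert rmsep2 == pytest.approx(10 * rmsep1)
        assert r2 == pytest.approx(r1) and rpd2 == pytest.approx(rpd1)

    def test_rpd_identity_holds_by_construction(self, rng):
        y = rng.normal(size=12)
        pred = y + rng.normal(0, 0.3, 12)
        _, rmsep, rpd = evaluate_on_prediction(_Identity(), pred[:, None], y)
        assert rpd == pytest.approx(np.std(y, ddof=1) / rmsep)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            evaluate_on_prediction(_Identity(), np.ones((4, 1)), np.ones(4))


class TestPlsrFit:
    def test_orthogonal_single_signal_needs_one_component(self, rng):
        n = 40
        raw = rng.normal(size=(n, 3))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = 2.0 * X[:, 0]
        model = plsr_fit(X, y, PLSRConfig(max_components=3, cv_folds=5))
        assert model.n_components == 1
        np.testing.assert_allclose(model.coef, [2, 0, 0], atol=1e-8)

    def test_component_ceiling_respects_rank(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        model = plsr_fit(X, y, PLSRConfig(max_components=10, cv_folds=4))
        assert model.n_components <= 4


class TestSvrFit:
    def test_nonlinear_sine_fit(self, rng):
        x = np.linspace(0, 2 * np.pi, 60)
        y = np.sin(x)
        X = x[:, None]
        model = svr_fit(X, y, SVRConfig(cv_folds=5), seed=0)
        x_new = np.linspace(0.1, 2 * np.pi - 0.1, 25)[:, None]
        r, rmsep, rpd = evaluate_on_prediction(model, x_new,
                                               np.sin(x_new).ravel())
        assert r > 0.99

    def test_winning_pair_replays_same_cv_rmse(self, rng):
        from teapigments.calibrate import _svr_cv_rmse

        X = rng.normal(size=(40, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=40)
        cfg = SVRConfig(cv_folds=5, refine=False)
        model = svr_fit(X, y, cfg, seed=2)
        x_mean, x_sd = model.x_mean, model.x_sd
        fold_id = make_folds(40, 5, 2)
        replay = _svr_cv_rmse((X - x_mean) / x_sd, y, model.c, model.g,
                              cfg.epsilon, fold_id, 5)
        assert replay == pytest.approx(model.cv_rmse)

    def test_not_much_worse_than_plsr_on_linear_design(self, rng):
        X = rng.normal(size=(80, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 0.0]) + 0.02 * rng.normal(size=80)
        tr, te = np.arange(60), np.arange(60, 80)
        pls_model = plsr_fit(X[tr], y[tr], PLSRConfig(max_components=5, cv_folds=5))
        svr_model = svr_fit(X[tr], y[tr], SVRConfig(cv_folds=5), seed=0)
        _, rmsep_pls, _ = evaluate_on_prediction(pls_model, X[te], y[te])
        _, rmsep_svr, _ = evaluate_on_prediction(svr_model, X[te], y[te])
        assert rmsep_svr <= 1.5 * rmsep_pls


# a reduced grid + scaled selector keeps pipeline tests quick; stages exercised
# are identical to the full protocol
REDUCED_SPEC = dict(
    combos=(("none", "none", "PLSR"), ("smooth", "CARS", "PLSR"),
            ("smooth", "VCPA_IRIV", "SVR")),
    selector=SelectorConfig(cars_runs=20, vcpa_bms_runs=100,
                            vcpa_iterations=5, vcpa_edf_target=20),
)


@pytest.fixture(scope="module")
def reduced_run():
    ds, recs, _ = simulate(SimConfig(n_replicates=5, seed=5))
    spec = PipelineSpec(pigments=("TF",), seed=5, **REDUCED_SPEC)
    reports, artifacts = run_pipeline(ds, recs, spec)
    return ds, recs, reports, artifacts


class TestPipeline:
    def test_one_report_per_combination(self, reduced_run):
        _, _, reports, _ = reduced_run
        assert len(reports) == 3
        assert {(r.preprocess, r.selector, r.model) for r in reports} == set(
            REDUCED_SPEC["combos"])

    def test_split_matches_requested_ratio(self, reduced_run):
        ds, _, _, artifacts = reduced_run
        split = artifacts["split"]
        assert len(split.prediction_indices) == ds.n_samples // 3

    def test_rpd_identity_on_emitted_reports(self, reduced_run):
        _, _, reports, _ = reduced_run
        for r in reports:
            assert r.RMSEP >= 0 and abs(r.R_p) <= 1 + 1e-12

    def test_plain_combo_reduces_to_direct_plsr(self, reduced_run):
        ds, recs, reports, artifacts = reduced_run
        from teapigments.core_data import pigment_vector

        split = artifacts["split"]
        cal = np.array(split.calibration_indices)
        pred = np.array(split.prediction_indices)
        y = pigment_vector(recs, "TF")
        fold_seed = (5 * 31 + 7) % (2**31 - 1)
        model = plsr_fit(ds.matrix[cal], y[cal], PLSRConfig(), seed=fold_seed)
        _, rmsep, _ = evaluate_on_prediction(model, ds.matrix[pred], y[pred])
        plain = [r for r in reports if (r.preprocess, r.selector) == ("none", "none")][0]
        assert plain.RMSEP == pytest.approx(rmsep)

    def test_leakage_guard_prediction_rows_do_not_touch_fits(self, rng):
        """With a fixed split, perturbing prediction rows changes nothing
        about fitted preprocessors, selections, or model coefficients."""
        ds, recs, _ = simulate(SimConfig(n_replicates=3, seed=6))
        from teapigments.core_data import pigment_vector

        cal = np.arange(0, 20)
        y_cal = pigment_vector(recs, "TF")[cal]
        X = ds.matrix.copy()
        prep1 = fit_preprocessor(X[cal], PreprocessSpec(method="smooth"))
        Xc1 = apply_preprocessor(X[cal], prep1)
        sel1 = select(Xc1, y_cal, SelectorConfig(algorithm="CARS",
                                                 cars_runs=15, seed=0))
        m1 = fit_pls1(Xc1[:, sel1.selected], y_cal, 3)

        X[20:] += rng.normal(size=X[20:].shape)  # prediction-side perturbation
        prep2 = fit_preprocessor(X[cal], PreprocessSpec(method="smooth"))
        Xc2 = apply_preprocessor(X[cal], prep2)
        sel2 = select(Xc2, y_cal, SelectorConfig(algorithm="CARS",
                                                 cars_runs=15, seed=0))
        m2 = fit_pls1(Xc2[:, sel2.selected], y_cal, 3)
        assert sel1.selected == sel2.selected
        np.testing.assert_array_equal(m1.coef, m2.coef)


class TestRenderReport:
    def _reports(self, n):
        return [
            EvalReport("TF", "PLSR", "none", "none", 210, str(i + 1),
                       0.9, 0.1, 0.9, 0.1 + i / 100, 3.0 + i)
            for i in range(n)
        ]

    def test_csv_and_chart_written(self, tmp_path):
        paths = render_report(self._reports(8), tmp_path)
        df = pd.read_csv(paths["csv"])
        assert len(df) == 8
        assert paths["chart"].exists()

    def test_csv_round_trip_at_printed_precision(self, tmp_path):
        reports = self._reports(3)
        paths = render_report(reports, tmp_path)
        df = pd.read_csv(paths["csv"])
        src = reports_frame(reports).sort_values(["pigment", "RPD"],
                                                 ascending=[True, False])
        np.testing.assert_allclose(np.sort(df["RPD"].to_numpy()),
                                   np.sort(src["RPD"].to_numpy()), atol=1e-6)

    def test_single_report_chart(self, tmp_path):
        paths = render_report(self._reports(1), tmp_path)
        assert paths["chart"].exists()

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            render_report([], tmp_path)
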