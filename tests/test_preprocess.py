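import itertools

import numpy as np
import pytest

from teapigments.preprocess import (
    PreprocessSpec,
    apply_preprocessor,
    fit_preprocessor,
    kennard_stone_split,
)


class TestMinMax:
    def test_learns_bounds_and_scales(self):
        X = np.array([[2.0], [4.0], [6.0]])
        fitted = fit_preprocessor(X, PreprocessSpec(method="minmax"))
        np.testing.assert_array_equal(fitted.col_min_, [2.0])
        np.testing.assert_array_equal(fitted.col_max_, [6.0])
        np.testing.assert_allclose(apply_preprocessor(X, fitted).ravel(),
                                   [0.0, 0.5, 1.0])

    def test_calibration_set_attains_0_and_1(self, rng):
        X = rng.normal(size=(20, 8))
        fitted = fit_preprocessor(X, PreprocessSpec(method="minmax"))
        out = apply_preprocessor(X, fitted)
        np.testing.assert_allclose(out.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=0), 1.0, atol=1e-12)

    def test_prediction_rows_may_leave_unit_interval(self, rng):
        X = rng.normal(size=(10, 3))
        fitted = fit_preprocessor(X, PreprocessSpec(method="minmax"))
        out = apply_preprocessor(X + 10.0, fitted)
        assert out.max() > 1.0  # permitted, by contract

    def test_constant_column_rejected_by_name(self, rng):
        X = rng.normal(size=(5, 4))
        X[:, 2] = 3.0
        with pytest.raises(ValueError, match="column 2"):
            fit_preprocessor(X, PreprocessSpec(method="minmax"))


class TestMSC:
    def test_rows_equal_to_mean_are_fixed_points(self):
        row = np.linspace(1, 5, 12)
        X = np.tile(row, (4, 1))
        fitted = fit_preprocessor(X, PreprocessSpec(method="msc", block_size=None))
        np.testing.assert_allclose(apply_preprocessor(X, fitted), X, atol=1e-10)

    def test_affine_distortion_is_removed(self, rng):
        m = rng.normal(size=30)
        X_cal = np.tile(m, (3, 1))
        fitted = fit_preprocessor(X_cal, PreprocessSpec(method="msc", block_size=None))
        distorted = (3.0 + 2.0 * m)[None, :]
        np.testing.assert_allclose(apply_preprocessor(distorted, fitted), m[None, :],
                                   atol=1e-10)

    def test_matches_per_row_least_squares_oracle(self, rng):
        X = rng.normal(size=(6, 210)) + np.linspace(0, 3, 210)
        fitted = fit_preprocessor(X, PreprocessSpec(method="msc", block_size=None))
        out = apply_preprocessor(X, fitted)
        m = X.mean(axis=0)
        A = np.column_stack([np.ones_like(m), m])
        for i in range(X.shape[0]):
            a, b = np.linalg.solve(A.T @ A, A.T @ X[i])
            np.testing.assert_allclose(out[i], (X[i] - a) / b, rtol=1e-8)

    def test_nonpositive_slope_rejected_with_row(self, rng):
        m = np.linspace(1, 2, 20)
        X_cal = np.tile(m, (3, 1))
        fitted = fit_preprocessor(X_cal, PreprocessSpec(method="msc", block_size=None))
        flipped = (5.0 - 2.0 * m)[None, :]
        with pytest.raises(ValueError, match="row 0"):
            apply_preprocessor(flipped, fitted)


class TestSmooth:
    def test_hand_computed_shrinking_edges(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        spec = PreprocessSpec(method="smooth", smooth_window=3, block_size=None)
        fitted = fit_preprocessor(X, spec)
        np.testing.assert_allclose(apply_preprocessor(X, fitted).ravel(),
                                   [1.5, 2.0, 3.0, 4.0, 4.5])

    def test_constant_signal_preserved_exactly(self):
        X = np.full((2, 30), 7.5)
        fitted = fit_preprocessor(X, PreprocessSpec(method="smooth"))
        np.testing.assert_array_equal(apply_preprocessor(X, fitted), X)

    def test_never_crosses_parameter_blocks(self, rng):
        X = rng.normal(size=(3, 10))
        spec = PreprocessSpec(method="smooth", smooth_window=3, block_size=5)
        fitted = fit_preprocessor(X, spec)
        out1 = apply_preprocessor(X, fitted)
        X2 = X.copy()
        X2[:, 5:] += 100.0  # second block shifted; first block must not move
        out2 = apply_preprocessor(X2, fitted)
        np.testing.assert_array_equal(out1[:, :5], out2[:, :5])

    def test_interior_mean_preserved(self, rng):
        X = rng.normal(size=(1, 30))
        fitted = fit_preprocessor(X, PreprocessSpec(method="smooth",
                                                    smooth_window=5))
        out = apply_preprocessor(X, fitted)
        # away from edges a centered moving average is mean-preserving up to
        # the edge-effect bound
        assert abs(out[0, 2:-2].mean() - X[0, 2:-2].mean()) < 0.5 * X.std()

    def test_even_or_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            PreprocessSpec(method="smooth", smooth_window=4)
        with pytest.raises(ValueError):
            PreprocessSpec(method="smooth", smooth_window=1)


class TestLeakage:
    def test_fit_state_independent_of_prediction_rows(self, rng):
        # spectrum-like rows (shared shape + positive gains) so MSC slopes
        # are well-defined
        base = np.linspace(1, 5, 10)
        X_cal = (rng.uniform(0.5, 2.0, (12, 1)) * base
                 + rng.uniform(-0.5, 0.5, (12, 1))
                 + 0.05 * rng.normal(size=(12, 10)))
        for method in ("msc", "minmax"):
            spec = PreprocessSpec(method=method, block_size=None)
            f1 = fit_preprocessor(X_cal, spec)
            X_pred = 1.5 * base + 0.05 * rng.normal(size=(5, 10))
            _ = apply_preprocessor(X_pred, f1)
            f2 = fit_preprocessor(X_cal, spec)
            if method == "msc":
                np.testing.assert_array_equal(f1.mean_spectrum_, f2.mean_spectrum_)
            else:
                np.testing.assert_array_equal(f1.col_min_, f2.col_min_)
                np.testing.assert_array_equal(f1.col_max_, f2.col_max_)


def brute_force_kennard_stone(X, n_cal):
    """Literal max-min re-scan oracle (O(n^3)), Euclidean metric."""
    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(X))
    n = len(X)
    i, j = np.unravel_index(np.argmax(D), D.shape)
    chosen = [min(i, j), max(i, j)]
    while len(chosen) < n_cal:
        best, best_d = None, -1.0
        for c in range(n):
            if c in chosen:
                continue
            d = min(D[c, k] for k in chosen)
            if d > best_d:
                best, best_d = c, d
        chosen.append(best)
    return sorted(chosen)


class TestKennardStone:
    def test_150_samples_split_100_50(self, full_sim):
        ds, _, _ = full_sim
        res = kennard_stone_split(ds.matrix, 2.0 / 3.0, metric="mahalanobis")
        assert len(res.calibration_indices) == 100
        assert len(res.prediction_indices) == 50
        assert set(res.calibration_indices) | set(res.prediction_indices) == set(range(150))

    def test_collinear_points_seed_with_extreme_pair(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        res = kennard_stone_split(X, 0.5, metric="euclidean")
        assert set(res.calibration_indices) == {0, 3}

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(12, 2))
            res = kennard_stone_split(X, 0.5, metric="euclidean")
            oracle = brute_force_kennard_stone(X, 12 - int(np.floor(12 * 0.5)))
            assert list(res.calibration_indices) == oracle

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(20, 4))
        perm = rng.permutation(20)
        base = kennard_stone_split(X, 0.6, metric="mahalanobis")
        permuted = kennard_stone_split(X[perm], 0.6, metric="mahalanobis")
        mapped = {int(np.flatnonzero(perm == i)[0])
                  for i in base.calibration_indices}
        assert set(permuted.calibration_indices) == mapped

    def test_singular_covariance_handled_by_ridge(self, rng):
        X = rng.normal(size=(5, 50))  # p >> n: singular covariance
        res = kennard_stone_split(X, 0.6, metric="mahalanobis")
        assert len(res.calibration_indices) == 3

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_bad_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            kennard_stone_split(np.eye(4), frac)
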