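"""Splitting, metrics, sigma grids and the grid search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirkpls import (KernelParams, KernelPLS, build_sigma_grid, cc,
                     compare_with_linear_pls, grid_search, rmse,
                     split_samples)
from nirkpls.selection import linear_pls_predict, select_linear_pls


class TestSplit:
    def test_248_samples_partition_120_64_64(self):
        split = split_samples(248, (120, 64, 64), seed=11)
        assert split.sizes == (120, 64, 64)
        union = np.concatenate([split.calibration, split.validation,
                                split.testing])
        assert sorted(union.tolist()) == list(range(248))

    def test_forced_partition_of_four(self):
        split = split_samples(4, (2, 1, 1), seed=0)
        assert sorted(np.concatenate([split.calibration, split.validation,
                                      split.testing]).tolist()) == [0, 1, 2, 3]

    def test_same_seed_reproduces_different_seed_differs(self):
        a = split_samples(100, (50, 25, 25), seed=5)
        b = split_samples(100, (50, 25, 25), seed=5)
        c = split_samples(100, (50, 25, 25), seed=6)
        np.testing.assert_array_equal(a.calibration, b.calibration)
        np.testing.assert_array_equal(a.testing, b.testing)
        assert not np.array_equal(a.calibration, c.calibration)

    def test_oversized_split_rejected(self):
        with pytest.raises(ValueError):
            split_samples(10, (6, 3, 3), seed=0)


class TestMetrics:
    def test_perfect_fit_gives_zero_rmse(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_rmse_hand_value_n_minus_1_denominator(self):
        # sum of squares = 8, n-1 = 1 -> sqrt(8)
        assert rmse([0.0, 2.0], [2.0, 0.0]) == pytest.approx(np.sqrt(8.0))

    def test_rmse_homogeneity(self, rng):
        y = rng.normal(size=10)
        yhat = rng.normal(size=10)
        assert rmse(3.5 * y, 3.5 * yhat) == pytest.approx(3.5 * rmse(y, yhat))

    def test_rmse_needs_two_samples(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0])

    def test_cc_affine_and_sign(self, rng):
        y = rng.normal(size=20)
        assert cc(y, 2 * y + 3) == pytest.approx(1.0)
        assert cc(y, -y) == pytest.approx(-1.0)

    def test_cc_hand_value(self):
        assert cc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_cc_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_metrics_invariant_under_joint_permutation(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        yhat = y + rng.normal(size=12)
        perm = rng.permutation(12)
        assert rmse(y[perm], yhat[perm]) == pytest.approx(rmse(y, yhat))
        assert cc(y[perm], yhat[perm]) == pytest.approx(cc(y, yhat))


class TestSigmaGrid:
    def test_reference_grid_has_6400_candidates(self):
        grid = build_sigma_grid(0.01, 64.0, 0.01)
        assert grid.size == 6400
        assert grid[0] == pytest.approx(0.01)
        assert grid[-1] == pytest.approx(64.0)

    def test_degenerate_single_point(self):
        np.testing.assert_allclose(build_sigma_grid(1.0, 1.0, 0.5), [1.0])

    def test_integer_count_formula(self):
        np.testing.assert_allclose(build_sigma_grid(0.5, 2.5, 0.5),
                                   [0.5, 1.0, 1.5, 2.0, 2.5])

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            build_sigma_grid(0.1, 1.0, 0.0)
        with pytest.raises(ValueError):
            build_sigma_grid(1.0, 0.5, 0.1)


@pytest.fixture(scope="module")
def split_problem():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(30, 4))
    y = np.sin(X[:, 0] * 2) + X[:, 1] ** 2 + 0.05 * rng.normal(size=30)
    return (X[:20], y[:20], X[20:], y[20:])


class TestGridSearch:
    def test_single_cell_grid_is_its_own_best(self, split_problem):
        X_cal, y_cal, X_val, y_val = split_problem
        surface = grid_search(X_cal, y_cal, X_val, y_val, [1.5], [3])
        assert surface.rmse_v.shape == (1, 1)
        assert surface.best["sigma"] == 1.5 and surface.best["s"] == 3
        assert surface.best["rmse_v"] == pytest.approx(surface.rmse_v[0, 0])

    def test_matches_exhaustive_double_loop_refit(self, split_problem):
        """Every surface cell equals an independent from-scratch refit."""
        X_cal, y_cal, X_val, y_val = split_problem
        sigma_grid = [0.5, 1.0, 2.0, 4.0, 8.0]
        s_grid = [2, 4, 6]
        surface = grid_search(X_cal, y_cal, X_val, y_val, sigma_grid, s_grid)
        best_oracle = None
        for i, sigma in enumerate(sigma_grid):
            for j, s in enumerate(s_grid):
                model = KernelPLS(KernelParams(sigma=sigma, s=s)).fit(X_cal, y_cal)
                r = rmse(y_val, model.predict(X_val).ravel())
                assert surface.rmse_v[i, j] == pytest.approx(r, abs=1e-10)
                if best_oracle is None or r < best_oracle[0]:
                    best_oracle = (r, sigma, s)
        assert surface.best["rmse_v"] == pytest.approx(best_oracle[0], abs=1e-10)
        assert (surface.best["sigma"], surface.best["s"]) == best_oracle[1:]

    def test_best_achieves_matrix_minimum(self, split_problem):
        X_cal, y_cal, X_val, y_val = split_problem
        surface = grid_search(X_cal, y_cal, X_val, y_val,
                              np.geomspace(0.1, 10, 6), [1, 2, 3])
        assert surface.best["rmse_v"] == pytest.approx(np.nanmin(surface.rmse_v))

    def test_long_format_export(self, split_problem, tmp_path):
        X_cal, y_cal, X_val, y_val = split_problem
        surface = grid_search(X_cal, y_cal, X_val, y_val, [0.5, 1.0], [1, 2])
        df = surface.to_frame()
        assert list(df.columns) == ["sigma", "s", "rmse_v", "cc_v"]
        assert len(df) == 4
        surface.to_csv(tmp_path / "surface.csv")
        assert (tmp_path / "surface.csv").exists()

    def test_s_above_calibration_rank_rejected(self, split_problem):
        X_cal, y_cal, X_val, y_val = split_problem
        with pytest.raises(ValueError):
            grid_search(X_cal, y_cal, X_val, y_val, [1.0], [len(y_cal)])


class TestLinearComparison:
    def test_noiseless_linear_data_fits_both_exactly(self, rng):
        X = rng.normal(size=(40, 6))
        beta = rng.normal(size=6)
        y = X @ beta
        X_cal, y_cal, X_val, y_val = X[:25], y[:25], X[25:], y[25:]
        assert rmse(y_val, linear_pls_predict(X_cal, y_cal, X_val, 6)) < 1e-8
        surface = grid_search(X_cal, y_cal, X_val, y_val,
                              [1e4 * np.abs(X).max()], [6])
        assert surface.best["rmse_v"] < 1e-2 * y.std()

    def test_nonlinear_data_favours_the_kernel_model(self, small_dataset):
        ds = small_dataset
        split = split_samples(60, (30, 15, 15), seed=3)
        X, ref = ds.spectra.X, ds.reference
        res = compare_with_linear_pls(
            X[split.calibration], ref.iloc[split.calibration],
            X[split.validation], ref.iloc[split.validation],
            np.geomspace(0.02, 20, 12), np.arange(1, 9))
        for analyte in ("SU", "VC", "OA"):
            assert res[analyte]["rbf_pls"].rmse < res[analyte]["pls"].rmse

    def test_shuffled_response_has_no_signal(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + 0.1 * rng.normal(size=40)
        y = rng.permutation(y)  # break the link
        X_cal, y_cal, X_val, y_val = X[:25], y[:25], X[25:], y[25:]
        pls_best = select_linear_pls(X_cal, y_cal, X_val, y_val, [1, 2, 3])
        surface = grid_search(X_cal, y_cal, X_val, y_val,
                              np.geomspace(0.5, 50, 5), [1, 2, 3])
        assert abs(pls_best["cc_v"]) < 0.6
        assert abs(surface.best["cc_v"]) < 0.6
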