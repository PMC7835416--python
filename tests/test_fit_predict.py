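"""Kernel-PLS training loop and prediction equation."""

import numpy as np
import pytest

from nirkpls import (KernelParams, KernelPLS, center_test_kernel,
                     center_train_kernel, fit, kernel_matrix, predict,
                     refinement_trace, rmse)
from nirkpls.selection import linear_pls_predict


def test_full_rank_interpolation_recovers_training_y(rng):
    X = rng.normal(size=(6, 4))
    y = rng.normal(size=6)
    model = fit(X, y, KernelParams(sigma=1.0, s=5))
    pred = model.predict(X).ravel()
    assert np.abs(pred - y).max() < 1e-8 * max(1.0, np.abs(y).max())


def test_interpolation_rmse_below_noise_floor(rng):
    # distinct rows, s = n-1: training RMSE under 1e-6 of SD(y)
    X = rng.normal(size=(10, 3))
    y = rng.normal(size=10)
    model = fit(X, y, KernelParams(sigma=2.0, s=9))
    assert rmse(y, model.predict(X).ravel()) < 1e-6 * y.std()


def test_duplicated_samples_get_identical_predictions(rng):
    X = rng.normal(size=(7, 4))
    X[3] = X[0]
    y = rng.normal(size=7)
    model = fit(X, y, KernelParams(sigma=1.5, s=3))
    pred = model.predict(X).ravel()
    assert pred[0] == pytest.approx(pred[3], abs=1e-9)


def test_constant_response_predicts_the_constant(rng):
    X = rng.normal(size=(8, 3))
    y = np.full(8, 4.2)
    model = fit(X, y, KernelParams(sigma=1.0, s=2))
    np.testing.assert_allclose(model.predict(rng.normal(size=(5, 3))), 4.2,
                               atol=1e-9)


def test_prediction_equation_matches_explicit_matrix_chain(rng):
    """Y' = M_any U (V^T M U)^-1 V^T Y, evaluated independently."""
    X = rng.normal(size=(8, 4))
    y = rng.normal(size=8)
    X_new = rng.normal(size=(3, 4))
    model = fit(X, y, KernelParams(sigma=1.2, s=3))

    K = kernel_matrix(X, X, 1.2)
    M = center_train_kernel(K)
    M_new = center_test_kernel(kernel_matrix(X_new, X, 1.2), K)
    U, V, Yc = model.U, model.V, model.Y_train
    chain = M_new @ U @ np.linalg.inv(V.T @ M @ U) @ V.T @ Yc + y.mean()
    np.testing.assert_allclose(model.predict(X_new), chain, atol=1e-9)
    # functional surface agrees with the method surface
    np.testing.assert_allclose(predict(model, M_new), chain, atol=1e-9)


def test_beats_mean_predictor_on_nonlinear_data():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(20, 4))
    y = np.sin(2 * X[:, 0]) + X[:, 1] ** 2
    X_val = rng.normal(size=(10, 4))
    y_val = np.sin(2 * X_val[:, 0]) + X_val[:, 1] ** 2
    model = fit(X, y, KernelParams(sigma=2.0, s=4))
    baseline = rmse(y_val, np.full(10, y.mean()))
    assert rmse(y_val, model.predict(X_val).ravel()) < baseline


def test_training_rmse_non_increasing_in_s(nonlinear_xy):
    X, y = nonlinear_xy
    model = fit(X, y, KernelParams(sigma=2.0, s=len(y) - 1))
    errors = [rmse(y, model.predict(X, n_components=s).ravel())
              for s in range(1, model.n_components_ + 1)]
    diffs = np.diff(errors)
    assert np.all(diffs <= 1e-10)


def test_permutation_equivariance(rng, nonlinear_xy):
    X, y = nonlinear_xy
    perm = rng.permutation(len(y))
    X_new = rng.normal(size=(5, X.shape[1]))
    p1 = fit(X, y, KernelParams(sigma=1.5, s=4)).predict(X_new)
    p2 = fit(X[perm], y[perm], KernelParams(sigma=1.5, s=4)).predict(X_new)
    np.testing.assert_allclose(p1, p2, atol=1e-8)


def test_large_sigma_matches_linear_pls(rng):
    """As sigma grows, M tends to a scaled centered Gram matrix and the
    kernel model collapses onto classical linear PLS."""
    X = rng.normal(size=(30, 6))
    y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=30)
    X_new = rng.normal(size=(10, 6))
    from scipy.spatial.distance import pdist
    sigma = 1e3 * pdist(X).max()
    for s in (2, 4):
        kernel_pred = fit(X, y, KernelParams(sigma=sigma, s=s)).predict(X_new).ravel()
        linear_pred = linear_pls_predict(X, y, X_new, s)
        rel = np.abs(kernel_pred - linear_pred).max() / np.abs(linear_pred).max()
        assert rel < 1e-2


def test_s_exceeding_n_minus_1_rejected(rng):
    with pytest.raises(ValueError):
        fit(rng.normal(size=(5, 2)), rng.normal(size=5),
            KernelParams(sigma=1.0, s=5))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        KernelParams(sigma=-1.0, s=2)
    with pytest.raises(ValueError):
        KernelParams(sigma=1.0, s=0)
    with pytest.raises(ValueError):
        KernelParams(sigma=1.0, s=2, tol=0.0)


def test_literal_k_variant_also_interpolates(rng):
    # the compatibility switch computes scores from the untouched K
    X = rng.normal(size=(8, 3))
    y = rng.normal(size=8)
    model = fit(X, y, KernelParams(sigma=1.0, s=7, literal_k=True))
    assert model.n_components_ >= 1
    assert np.all(np.isfinite(model.predict(X)))


def test_score_columns_are_unit_norm_and_orthogonal(nonlinear_xy):
    X, y = nonlinear_xy
    model = fit(X, y, KernelParams(sigma=2.0, s=5))
    np.testing.assert_allclose(np.linalg.norm(model.V, axis=0), 1.0, atol=1e-9)
    np.testing.assert_allclose(np.linalg.norm(model.U, axis=0), 1.0, atol=1e-9)
    gram = model.V.T @ model.V
    np.testing.assert_allclose(gram, np.eye(model.n_components_), atol=1e-8)


def test_validation_trace_recorded_during_fit(nonlinear_xy):
    X, y = nonlinear_xy
    model = KernelPLS(KernelParams(sigma=2.0, s=4)).fit(
        X[:20], y[:20], X_val=X[20:], Y_val=y[20:])
    assert len(model.trace) >= 4
    assert np.all(np.isfinite(model.trace))


@pytest.mark.parametrize("mode", ["restart", "sweep"])
def test_refinement_trace_best_so_far_non_increasing(nonlinear_xy, mode):
    X, y = nonlinear_xy
    per_iter, best = refinement_trace(X[:20], y[:20], X[20:], y[20:],
                                      KernelParams(sigma=2.0, s=4, seed=3),
                                      n_iter=50, mode=mode)
    assert per_iter.size == best.size == 50
    assert np.all(np.diff(best) <= 0)


def test_model_roundtrips_through_archive(tmp_path, nonlinear_xy):
    X, y = nonlinear_xy
    model = fit(X, y, KernelParams(sigma=2.0, s=3))
    path = tmp_path / "model.npz"
    model.save(path)
    back = KernelPLS.load(path)
    np.testing.assert_array_equal(back.U, model.U)
    np.testing.assert_array_equal(back.predict(X), model.predict(X))
    assert back.params == model.params
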