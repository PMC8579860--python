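"""Metamodels: kernel ridge closed form, SVR dual, network training, search."""

import numpy as np
import pytest

from vimtarget.metamodels import (
    ConditioningError,
    DNNConfig,
    DNNRegressor,
    HyperparamGrid,
    RKHSRegressor,
    SVRRegressor,
    Standardizer,
    fit_dnn,
    fit_rkhs,
    fit_svr_axis,
    gaussian_kernel,
    greedy_feature_selection_rkhs,
    grid_search,
    kernel_matrix,
)

from _oracles import kernel_ridge_numeric, rbf_gram, svr_dual_qp, svr_predict


# ---------------------------------------------------------------------------
# Gaussian kernel


def test_gaussian_kernel_values(rng):
    x = rng.normal(size=5)
    assert gaussian_kernel(x, x, 2.0) == 1.0
    # ||x - y|| = sigma * sqrt(2)  ->  exp(-1)
    sigma = 1.7
    y = x.copy()
    y[0] += sigma * np.sqrt(2.0)
    assert gaussian_kernel(x, y, sigma) == pytest.approx(np.exp(-1.0))
    for _ in range(10):
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert gaussian_kernel(a, b, 1.3) == pytest.approx(gaussian_kernel(b, a, 1.3))
        assert 0.0 < gaussian_kernel(a, b, 1.3) <= 1.0


def test_gaussian_kernel_rejects_bad_sigma():
    with pytest.raises(ValueError):
        gaussian_kernel([0.0], [1.0], 0.0)


# ---------------------------------------------------------------------------
# kernel ridge (RKHS)


def test_rkhs_single_point_interpolates():
    m = fit_rkhs([[1.0, 2.0]], [5.0], sigma=1.0, ridge_lambda=1e-12, standardize=False)
    assert m.predict([[1.0, 2.0]])[0, 0] == pytest.approx(5.0, abs=1e-9)


def test_rkhs_interpolation_limit(rng):
    X = rng.normal(size=(5, 4))
    y = rng.normal(size=5)
    m = fit_rkhs(X, y, sigma=2.0, ridge_lambda=1e-12, standardize=False)
    np.testing.assert_allclose(m.predict(X)[:, 0], y, atol=1e-6)


def test_rkhs_matches_numeric_minimisation(rng):
    X = rng.normal(size=(6, 54))
    y = rng.normal(size=6)
    sigma, lam = np.sqrt(54.0), 1e-2
    m = fit_rkhs(X, y, sigma, lam, standardize=False)
    K = rbf_gram(X, X, sigma)
    alpha_ref = kernel_ridge_numeric(K, y, lam)
    np.testing.assert_allclose(m.coefficients_alpha[:, 0], alpha_ref, atol=1e-5)
    Xq = rng.normal(size=(4, 54))
    np.testing.assert_allclose(
        m.predict(Xq)[:, 0], rbf_gram(Xq, X, sigma) @ alpha_ref, atol=1e-5
    )


def test_rkhs_duplicate_inputs_at_zero_lambda_raise():
    X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 1.0]])
    with pytest.raises(ConditioningError):
        fit_rkhs(X, [1.0, 2.0, 3.0], sigma=1.0, ridge_lambda=0.0, standardize=False)


def test_rkhs_kernel_decay_toward_target_mean(rng):
    # far from all training points the kernel vanishes, so the prediction
    # falls back to the standardized-target origin, i.e. the training mean
    X = rng.normal(size=(6, 3))
    Y = rng.normal(size=(6, 3)) + 10.0
    model = RKHSRegressor(sigma=1.0, ridge_lambda=1e-3).fit(X, Y)
    far = model.predict(np.full((1, 3), 1e3))
    np.testing.assert_allclose(far[0], Y.mean(axis=0), atol=1e-6)


# ---------------------------------------------------------------------------
# SVR


def test_svr_flat_data_inside_tube_has_zero_duals(rng):
    X = rng.normal(size=(10, 4))
    y = 3.0 + rng.uniform(-0.05, 0.05, size=10)
    m = fit_svr_axis(X, y, sigma=2.0, epsilon=0.2, C=10.0, standardize=False)
    assert m.dual_coefficients.size == 0  # the flat function is optimal
    pred = m.predict(X)
    assert np.all(np.abs(pred - y) <= 0.2 + 1e-9)


def test_svr_kkt_conditions_hold(rng):
    X = rng.normal(size=(12, 6))
    y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=12)
    m = fit_svr_axis(X, y, sigma=2.0, epsilon=0.05, C=5.0, standardize=False, tol=1e-10)
    kkt = m.kkt_residuals
    assert kkt["sum_dual"] < 1e-6
    assert kkt["box_violation"] <= 0.0 + 1e-12
    assert kkt["inside_tube_violation"] < 1e-6
    assert np.all(np.abs(m.dual_coefficients) <= 5.0 + 1e-9)


def test_svr_matches_dense_qp_oracle(rng):
    n, sigma, eps, C = 7, 2.0, 0.1, 10.0
    X = rng.normal(size=(n, 5))
    y = rng.normal(size=n)
    m = fit_svr_axis(X, y, sigma, eps, C, standardize=False, tol=1e-10)
    dual, bias = svr_dual_qp(rbf_gram(X, X, sigma), y, eps, C)
    Xq = rng.normal(size=(5, 5))
    np.testing.assert_allclose(
        m.predict(Xq), svr_predict(Xq, X, dual, bias, sigma), atol=1e-4
    )


def test_svr_training_point_within_tube_at_large_C(rng):
    X = rng.normal(size=(8, 4))
    y = X[:, 0] ** 2
    m = fit_svr_axis(X, y, sigma=2.0, epsilon=0.1, C=1e3, standardize=False, tol=1e-10)
    assert np.all(np.abs(m.predict(X) - y) <= 0.1 + 1e-6)


def test_svr_support_set_shrinks_with_epsilon(rng):
    X = rng.normal(size=(20, 5))
    y = np.sin(X[:, 0]) + 0.3 * X[:, 1]
    sizes = []
    for eps in (0.0, 0.1, 0.3, 0.6):
        m = fit_svr_axis(X, y, sigma=2.0, epsilon=eps, C=10.0, standardize=False)
        sizes.append(m.dual_coefficients.size)
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# standardization equivariance


def test_standardization_equivariance_rkhs_and_svr(rng):
    X = rng.normal(size=(10, 6)) * np.array([1, 10, 100, 1, 5, 0.1])
    y = rng.normal(size=10) * 7 + 3
    xs, ys = Standardizer.fit(X), Standardizer.fit(y[:, None])
    Xs, Ys = xs.transform(X), ys.transform(y[:, None])[:, 0]
    Xq = rng.normal(size=(4, 6)) * np.array([1, 10, 100, 1, 5, 0.1])

    auto = fit_rkhs(X, y, sigma=2.0, ridge_lambda=1e-2)  # standardizes internally
    manual = fit_rkhs(Xs, Ys, sigma=2.0, ridge_lambda=1e-2, standardize=False)
    np.testing.assert_allclose(
        auto.predict(Xq)[:, 0],
        ys.inverse(manual.predict(xs.transform(Xq)))[:, 0],
        atol=1e-8,
    )

    auto_svr = fit_svr_axis(X, y, sigma=2.0, epsilon=0.1, C=10.0, tol=1e-10)
    manual_svr = fit_svr_axis(Xs, Ys, sigma=2.0, epsilon=0.1, C=10.0,
                              standardize=False, tol=1e-10)
    np.testing.assert_allclose(
        auto_svr.predict(Xq),
        ys.inverse(manual_svr.predict(xs.transform(Xq))[:, None])[:, 0],
        atol=1e-8,
    )


# ---------------------------------------------------------------------------
# DNN


def test_dnn_architecture_and_determinism(rng):
    X = rng.normal(size=(30, 54))
    Y = rng.normal(size=(30, 3))
    cfg = DNNConfig(seed=9, epochs=50)
    m1, m2 = fit_dnn(X, Y, cfg), fit_dnn(X, Y, cfg)
    shapes = [(A.shape, b.shape) for A, b in m1.layers]
    assert shapes == [((54, 256), (256,)), ((256, 128), (128,)),
                      ((128, 64), (64,)), ((64, 3), (3,))]
    for (A1, b1), (A2, b2) in zip(m1.layers, m2.layers):
        np.testing.assert_array_equal(A1, A2)
        np.testing.assert_array_equal(b1, b2)
    assert np.isfinite(m1.final_loss)


def test_dnn_learns_constant_target(rng):
    X = rng.normal(size=(25, 54))
    Y = np.tile([[2.0, -1.0, 0.5]], (25, 1))
    m = fit_dnn(X, Y + rng.normal(0, 1e-9, Y.shape), DNNConfig(seed=1, epochs=200))
    np.testing.assert_allclose(m.predict(X), Y, atol=1e-3)


# ---------------------------------------------------------------------------
# grid search and feature selection


def _toy_groups(n):
    return np.repeat([f"P{i}" for i in range(n // 2)], 2)


def test_grid_search_single_cell_returns_it(rng):
    X = rng.normal(size=(12, 54))
    Y = rng.normal(size=(12, 3))
    grid = HyperparamGrid(sigma=(3.0,), ridge_lambda=(0.1,))
    res = grid_search(X, Y, _toy_groups(12), kind="rkhs", grid=grid)
    assert res.best_params == {"sigma": 3.0, "ridge_lambda": 0.1}
    assert len(res.table) == 1


def test_grid_search_argmin_and_determinism(noiseless_cohort):
    ds = noiseless_cohort.clean
    res1 = grid_search(ds.X, ds.Y, ds.patient_ids, kind="rkhs", n_splits=5)
    res2 = grid_search(ds.X, ds.Y, ds.patient_ids, kind="rkhs", n_splits=5)
    assert res1.best_params == res2.best_params
    assert res1.best_error == res1.table["mean_error_mm"].min()


def test_grid_search_svr_smoke(noiseless_cohort):
    ds = noiseless_cohort.clean
    grid = HyperparamGrid(sigma=(np.sqrt(54.0),), epsilon=(0.05, 0.2), cost_C=(1.0, 10.0))
    res = grid_search(ds.X, ds.Y, ds.patient_ids, kind="svr", grid=grid, n_splits=5)
    assert set(res.best_params) == {"sigma", "epsilon", "C"}
    assert len(res.table) == 4


def test_greedy_selection_finds_the_informative_feature(rng):
    n = 40
    X = rng.normal(size=(n, 10))
    signal = X[:, 7]
    Y = np.column_stack([signal, 2 * signal, -signal])
    selected, trace = greedy_feature_selection_rkhs(
        X, Y, _toy_groups(n), ridge_lambda=1e-4
    )
    assert selected[0] == 7
    assert trace[-1] < 0.2 * trace[0]


def test_greedy_selection_tie_breaks_to_first_duplicate(rng):
    n = 40
    base = rng.normal(size=n)
    X = np.column_stack([rng.normal(size=n), base, base, rng.normal(size=n)])
    Y = np.column_stack([base, base, base])
    selected, _ = greedy_feature_selection_rkhs(X, Y, _toy_groups(n), ridge_lambda=1e-4)
    assert 1 in selected and 2 not in selected


def test_greedy_selection_stops_on_pure_noise(rng):
    X = rng.normal(size=(30, 8))
    Y = rng.normal(size=(30, 3))
    selected, trace = greedy_feature_selection_rkhs(X, Y, _toy_groups(30))
    assert len(selected) <= 1
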