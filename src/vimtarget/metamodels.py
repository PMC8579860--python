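"""Regression metamodels mapping the 54-value landmark vector to a 3-D target.

Three families are provided, all operating on standardized features and
per-axis standardized targets:

* **Kernel ridge regression in an RKHS** with a Gaussian kernel
  ``K(x, y) = exp(-||x - y||^2 / (2 sigma^2))``.  The fitted function is
  ``F(x) = sum_i alpha_i K(x, X_i)`` with coefficients minimizing
  ``(1/n) sum_i (F(X_i) - y_i)^2 + lambda ||F||_H^2``, whose closed form is
  ``alpha = (K + n lambda I)^{-1} y``.
* **epsilon-insensitive support vector regression**, one model per output
  axis, solving the standard SVR dual (box constraints at C, dual
  coefficients summing to zero) with the same Gaussian kernel.  The dual is
  solved by libsvm's SMO via scikit-learn; support vectors, dual
  coefficients and bias are exposed so Karush-Kuhn-Tucker residuals can be
  audited.
* **A small feed-forward network** with hidden layers 256/128/64, ReLU
  activations and a linear 3-unit output, trained with Adam under squared
  error.  Training is deterministic given the configured seed; the fitted
  weights are stored explicitly so prediction is an auditable numpy forward
  pass.

Hyperparameters (kernel width, ridge weight, tube width, cost) are selected
by exhaustive grid search scored with grouped cross-validation so that the
two hemispheres of a patient never straddle a train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "Standardizer",
    "RKHSModel",
    "SVRAxisModel",
    "DNNConfig",
    "DNNModel",
    "HyperparamGrid",
    "GridSearchResult",
    "RKHSRegressor",
    "SVRRegressor",
    "DNNRegressor",
    "ConditioningError",
    "DivergenceError",
    "gaussian_kernel",
    "kernel_matrix",
    "fit_rkhs",
    "fit_svr_axis",
    "fit_dnn",
    "grid_search",
    "greedy_feature_selection_rkhs",
    "grouped_folds",
]


class ConditioningError(np.linalg.LinAlgError):
    """The kernel system is singular (e.g. duplicate inputs at lambda = 0)."""


class DivergenceError(RuntimeError):
    """Network training produced a non-finite loss."""


# ---------------------------------------------------------------------------
# standardization


@dataclass(frozen=True)
class Standardizer:
    """Per-column centring and unit-variance scaling, with a floor on the scale.

    Constant columns get scale 1 so they pass through centred but unscaled.
    """

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        return cls(center=center, scale=scale)

    @classmethod
    def identity(cls, n_features: int) -> "Standardizer":
        return cls(center=np.zeros(n_features), scale=np.ones(n_features))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale + self.center


def _as_2d(X: Sequence) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


# ---------------------------------------------------------------------------
# Gaussian kernel


def gaussian_kernel(x: Sequence[float], y: Sequence[float], sigma: float) -> float:
    """``exp(-||x - y||^2 / (2 sigma^2))`` for two equal-length vectors."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.exp(-np.sum((x - y) ** 2) / (2.0 * sigma**2)))


def kernel_matrix(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel Gram matrix between the rows of A and the rows of B."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    d2 = cdist(_as_2d(A), _as_2d(B), "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# kernel ridge regression (RKHS)


def _solve_kernel_ridge(K: np.ndarray, Y: np.ndarray, ridge_lambda: float) -> np.ndarray:
    """alpha = (K + n lambda I)^{-1} Y, the minimiser of the regularized loss.

    The loss carries a 1/n factor on the squared-error term, hence the
    ``n * lambda`` shift on the Gram matrix.
    """
    import scipy.linalg

    n = K.shape[0]
    system = K + n * ridge_lambda * np.eye(n)
    try:
        return scipy.linalg.solve(system, Y, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            f"kernel system is singular (n={n}, lambda={ridge_lambda}); "
            "duplicate inputs with lambda ~ 0?"
        ) from exc


@dataclass(frozen=True)
class RKHSModel:
    """One fitted kernel-ridge axis model: F(x) = sum_i alpha_i K(x, X_i)."""

    training_inputs: np.ndarray  # standardized, (n, p)
    coefficients_alpha: np.ndarray  # (n,) or (n, k) for multi-axis
    kernel_sigma: float
    ridge_lambda: float
    x_standardizer: Standardizer
    y_standardizer: Standardizer

    def predict(self, X: Sequence) -> np.ndarray:
        Xs = self.x_standardizer.transform(_as_2d(X))
        K = kernel_matrix(Xs, self.training_inputs, self.kernel_sigma)
        raw = K @ self.coefficients_alpha
        return self.y_standardizer.inverse(raw)


def fit_rkhs(
    X: Sequence,
    y: Sequence[float],
    sigma: float,
    ridge_lambda: float,
    standardize: bool = True,
) -> RKHSModel:
    """Fit a single-axis Gaussian kernel ridge model in closed form.

    ``sigma`` is expressed in standardized feature units when ``standardize``
    is on (the default); ``ridge_lambda`` is dimensionless and enters as
    ``n * lambda`` on the Gram diagonal per the 1/n-weighted loss.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    xs = Standardizer.fit(X) if standardize else Standardizer.identity(X.shape[1])
    ys = Standardizer.fit(y[:, None]) if standardize else Standardizer.identity(1)
    Xs = xs.transform(X)
    Ys = ys.transform(y[:, None])
    K = kernel_matrix(Xs, Xs, sigma)
    alpha = _solve_kernel_ridge(K, Ys, ridge_lambda)
    return RKHSModel(
        training_inputs=Xs,
        coefficients_alpha=alpha,
        kernel_sigma=float(sigma),
        ridge_lambda=float(ridge_lambda),
        x_standardizer=xs,
        y_standardizer=ys,
    )


# ---------------------------------------------------------------------------
# epsilon-insensitive SVR


@dataclass(frozen=True)
class SVRAxisModel:
    """One fitted SVR axis: F(x) = sum_i (a_i - a_i*) K(x, X_i) + b.

    ``dual_coefficients`` holds (a_i - a_i*) for the support inputs only;
    training inputs with zero dual coefficient are dropped.  KKT residuals
    measured at fit time are kept for audit.
    """

    support_inputs: np.ndarray  # standardized, (n_sv, p)
    dual_coefficients: np.ndarray  # (n_sv,)
    bias_b: float
    kernel_sigma: float
    epsilon_tube: float
    cost_C: float
    x_standardizer: Standardizer
    y_standardizer: Standardizer
    kkt_residuals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kernel_sigma <= 0 or self.cost_C <= 0:
            raise ValueError("kernel_sigma and cost_C must be > 0")
        if self.epsilon_tube < 0:
            raise ValueError("epsilon_tube must be >= 0")
        if np.any(np.abs(self.dual_coefficients) > self.cost_C * (1 + 1e-9)):
            raise ValueError("dual coefficients exceed the box constraint |a - a*| <= C")

    def decision(self, Xs: np.ndarray) -> np.ndarray:
        """Standardized-space prediction for standardized inputs."""
        K = kernel_matrix(Xs, self.support_inputs, self.kernel_sigma)
        return K @ self.dual_coefficients + self.bias_b

    def predict(self, X: Sequence) -> np.ndarray:
        Xs = self.x_standardizer.transform(_as_2d(X))
        raw = self.decision(Xs)
        return self.y_standardizer.inverse(raw[:, None])[:, 0]


def _kkt_report(
    Xs: np.ndarray,
    ys: np.ndarray,
    dual_full: np.ndarray,
    bias: float,
    sigma: float,
    epsilon: float,
    C: float,
) -> dict:
    """KKT residuals of an SVR dual solution over the full training set.

    * ``sum_dual``: |sum_i (a_i - a_i*)| (equality constraint).
    * ``box_violation``: max(0, |beta_i| - C).
    * ``inside_tube_violation``: largest |beta_i| among points strictly
      inside the epsilon tube by more than the complementarity slack.
    """
    K = kernel_matrix(Xs, Xs, sigma)
    fitted = K @ dual_full + bias
    resid = ys - fitted
    slack = 1e-6
    inside = np.abs(resid) < epsilon - slack if epsilon > 0 else np.zeros_like(ys, bool)
    return {
        "sum_dual": float(abs(dual_full.sum())),
        "box_violation": float(max(0.0, np.max(np.abs(dual_full)) - C)),
        "inside_tube_violation": float(
            np.max(np.abs(dual_full[inside])) if inside.any() else 0.0
        ),
        "max_abs_residual": float(np.max(np.abs(resid))),
    }


def fit_svr_axis(
    X: Sequence,
    y: Sequence[float],
    sigma: float,
    epsilon: float,
    C: float,
    standardize: bool = True,
    tol: float = 1e-8,
    max_iter: int = -1,
) -> SVRAxisModel:
    """Fit one output axis by solving the Gaussian-kernel SVR dual.

    The dual — maximise ``-1/2 b' K b - epsilon |b|_1 + y' b`` over
    ``b_i = a_i - a_i*`` with ``sum b = 0`` and ``|b_i| <= C`` — is solved by
    sequential minimal optimization (libsvm).  ``sigma`` and ``epsilon`` are
    in standardized feature/target units when ``standardize`` is on.
    """
    from sklearn.svm import SVR as _SVR

    if sigma <= 0 or C <= 0:
        raise ValueError("sigma and C must be > 0")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.shape[0] < 2:
        raise ValueError("SVR requires at least 2 training samples")
    xs = Standardizer.fit(X) if standardize else Standardizer.identity(X.shape[1])
    ys = Standardizer.fit(y[:, None]) if standardize else Standardizer.identity(1)
    Xs = xs.transform(X)
    Ys = ys.transform(y[:, None])[:, 0]

    svr = _SVR(
        kernel="rbf",
        gamma=1.0 / (2.0 * sigma**2),
        C=C,
        epsilon=epsilon,
        tol=tol,
        cache_size=64,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svr.fit(Xs, Ys)

    dual_full = np.zeros(X.shape[0])
    dual_full[svr.support_] = svr.dual_coef_[0]
    bias = float(svr.intercept_[0])
    kkt = _kkt_report(Xs, Ys, dual_full, bias, sigma, epsilon, C)

    keep = np.abs(dual_full) > 0
    return SVRAxisModel(
        support_inputs=Xs[keep],
        dual_coefficients=dual_full[keep],
        bias_b=bias,
        kernel_sigma=float(sigma),
        epsilon_tube=float(epsilon),
        cost_C=float(C),
        x_standardizer=xs,
        y_standardizer=ys,
        kkt_residuals=kkt,
    )


# ---------------------------------------------------------------------------
# feed-forward network


@dataclass(frozen=True)
class DNNConfig:
    """Training configuration for the 54 -> 256 -> 128 -> 64 -> 3 network.

    ``batch_size=None`` means full batch for fewer than 512 samples and 512
    otherwise.  The seed is mandatory: it fixes the weight initialisation and
    any minibatch shuffling, making training reproducible.
    """

    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    learning_rate: float = 1e-3
    epochs: int = 500
    batch_size: int | None = None
    seed: int = 0
    l2_alpha: float = 0.0

    def resolved_batch(self, n: int) -> int:
        if self.batch_size is not None:
            return min(self.batch_size, n)
        return n if n < 512 else 512


@dataclass(frozen=True)
class DNNModel:
    """Fitted network: explicit (weights, bias) per layer, ReLU on hidden layers."""

    layers: tuple[tuple[np.ndarray, np.ndarray], ...]
    config: DNNConfig
    x_standardizer: Standardizer
    y_standardizer: Standardizer
    final_loss: float = float("nan")

    def predict(self, X: Sequence) -> np.ndarray:
        a = self.x_standardizer.transform(_as_2d(X))
        n_layers = len(self.layers)
        for i, (A, b) in enumerate(self.layers):
            a = a @ A + b
            if i < n_layers - 1:
                a = np.maximum(a, 0.0)  # ReLU
        return self.y_standardizer.inverse(a)


def fit_dnn(X: Sequence, Y: Sequence, config: DNNConfig) -> DNNModel:
    """Train the feed-forward metamodel under squared error with Adam.

    Features and each target axis are standardized before training and the
    outputs de-standardized at prediction.  Raises :class:`DivergenceError`
    if training ends with a non-finite loss.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPRegressor

    X = _as_2d(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    xs = Standardizer.fit(X)
    ys = Standardizer.fit(Y)
    Xs = xs.transform(X)
    Ys = ys.transform(Y)

    mlp = MLPRegressor(
        hidden_layer_sizes=config.hidden_sizes,
        activation="relu",
        solver="adam",
        alpha=config.l2_alpha,
        batch_size=config.resolved_batch(n),
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        shuffle=True,
        random_state=config.seed,
        tol=0.0,
        n_iter_no_change=config.epochs + 1,
        early_stopping=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(Xs, Ys if Ys.shape[1] > 1 else Ys[:, 0])

    if not np.isfinite(mlp.loss_):
        raise DivergenceError(f"non-finite training loss under config {config}")

    layers = tuple(
        (np.asarray(A, dtype=float), np.asarray(b, dtype=float))
        for A, b in zip(mlp.coefs_, mlp.intercepts_)
    )
    return DNNModel(
        layers=layers,
        config=config,
        x_standardizer=xs,
        y_standardizer=ys,
        final_loss=float(mlp.loss_),
    )


# ---------------------------------------------------------------------------
# multi-axis regressor wrappers (the interface the evaluation layer consumes)


class RKHSRegressor:
    """Three-axis kernel ridge metamodel; one closed-form solve, shared kernel."""

    kind = "rkhs"

    def __init__(self, sigma: float, ridge_lambda: float):
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        if ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        self.sigma = float(sigma)
        self.ridge_lambda = float(ridge_lambda)
        self.model_: RKHSModel | None = None

    def get_params(self) -> dict:
        return {"sigma": self.sigma, "ridge_lambda": self.ridge_lambda}

    def fit(self, X: Sequence, Y: Sequence) -> "RKHSRegressor":
        X = _as_2d(X)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        xs = Standardizer.fit(X)
        ys = Standardizer.fit(Y)
        Xs = xs.transform(X)
        Ys = ys.transform(Y)
        K = kernel_matrix(Xs, Xs, self.sigma)
        alpha = _solve_kernel_ridge(K, Ys, self.ridge_lambda)
        self.model_ = RKHSModel(
            training_inputs=Xs,
            coefficients_alpha=alpha,
            kernel_sigma=self.sigma,
            ridge_lambda=self.ridge_lambda,
            x_standardizer=xs,
            y_standardizer=ys,
        )
        return self

    def predict(self, X: Sequence) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("model is not fitted")
        return self.model_.predict(X)


class SVRRegressor:
    """Coordinate-by-coordinate epsilon-SVR metamodel (one axis model each).

    ``max_iter`` bounds the SMO iteration count per axis fit; the default is
    ample for cohort-scale problems (hundreds of samples) while keeping
    repeated cross-validation fits cheap.  Pass ``max_iter=-1`` for an
    unbounded exact solve.
    """

    kind = "svr"

    def __init__(self, sigma: float, epsilon: float, C: float,
                 tol: float = 1e-4, max_iter: int = 20_000):
        self.sigma = float(sigma)
        self.epsilon = float(epsilon)
        self.C = float(C)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.axis_models_: list[SVRAxisModel] | None = None

    def get_params(self) -> dict:
        return {"sigma": self.sigma, "epsilon": self.epsilon, "C": self.C}

    def fit(self, X: Sequence, Y: Sequence) -> "SVRRegressor":
        X = _as_2d(X)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.axis_models_ = [
            fit_svr_axis(X, Y[:, j], self.sigma, self.epsilon, self.C,
                         tol=self.tol, max_iter=self.max_iter)
            for j in range(Y.shape[1])
        ]
        return self

    def predict(self, X: Sequence) -> np.ndarray:
        if self.axis_models_ is None:
            raise RuntimeError("model is not fitted")
        return np.column_stack([m.predict(X) for m in self.axis_models_])


class NestedGridSearchRegressor:
    """Re-optimizes the hyperparameter grid on every training set it is fit on.

    Used for nested cross-validation: the outer CV driver passes the
    training fold's patient ids to ``fit``, an inner grouped-CV grid search
    picks the hyperparameters, and the winning model is refit on the whole
    fold.  This removes hyperparameter-selection leakage at the cost of one
    full grid search per outer fold.
    """

    def __init__(self, kind: str = "rkhs", grid: "HyperparamGrid | None" = None,
                 n_splits: int | None = None):
        if kind not in ("rkhs", "svr"):
            raise ValueError("nested grid search supports 'rkhs' and 'svr'")
        self.kind = kind
        self.grid = grid
        self.n_splits = n_splits
        self.best_params_: dict | None = None
        self.model_ = None

    def get_params(self) -> dict:
        return {"kind": self.kind, "n_splits": self.n_splits}

    def fit(self, X: Sequence, Y: Sequence, groups: Sequence | None = None):
        if groups is None:
            raise ValueError("nested grid search requires group labels at fit time")
        res = grid_search(X, Y, groups, kind=self.kind, grid=self.grid,
                          n_splits=self.n_splits)
        self.best_params_ = res.best_params
        if self.kind == "rkhs":
            self.model_ = RKHSRegressor(**res.best_params).fit(X, Y)
        else:
            self.model_ = SVRRegressor(
                sigma=res.best_params["sigma"], epsilon=res.best_params["epsilon"],
                C=res.best_params["C"],
            ).fit(X, Y)
        return self

    def predict(self, X: Sequence) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("model is not fitted")
        return self.model_.predict(X)


class DNNRegressor:
    """Feed-forward metamodel wrapper around :func:`fit_dnn`."""

    kind = "dnn"

    def __init__(self, config: DNNConfig | None = None, **overrides):
        self.config = replace(config or DNNConfig(), **overrides)
        self.model_: DNNModel | None = None

    def get_params(self) -> dict:
        return {"config": self.config}

    def fit(self, X: Sequence, Y: Sequence) -> "DNNRegressor":
        self.model_ = fit_dnn(X, Y, self.config)
        return self

    def predict(self, X: Sequence) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("model is not fitted")
        return self.model_.predict(X)


# ---------------------------------------------------------------------------
# grouped folds, grid search, feature selection


def grouped_folds(
    groups: Sequence, n_splits: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic grouped CV folds over sample indices.

    Groups (patient ids) are sorted; with ``n_splits=None`` every group gets
    its own test fold (leave-one-patient-out), otherwise the sorted groups
    are partitioned into ``n_splits`` contiguous blocks.  Both hemispheres of
    a patient always share a fold.
    """
    groups = np.asarray(groups)
    unique = np.array(sorted(set(groups.tolist())))
    if n_splits is None or n_splits >= len(unique):
        blocks = [np.array([g]) for g in unique]
    else:
        if n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        blocks = np.array_split(unique, n_splits)
    folds = []
    for block in blocks:
        test = np.flatnonzero(np.isin(groups, block))
        train = np.flatnonzero(~np.isin(groups, block))
        folds.append((train, test))
    return folds


@dataclass(frozen=True)
class HyperparamGrid:
    """Candidate hyperparameter lists, in standardized feature/target units.

    Kernel widths scale with sqrt(54) because squared distances between
    standardized 54-vectors concentrate around that magnitude.
    """

    sigma: tuple[float, ...] = tuple(np.sqrt(54.0) * np.array([0.5, 1.0, 2.0, 4.0, 8.0]))
    ridge_lambda: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    epsilon: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2)
    cost_C: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)

    def __post_init__(self) -> None:
        for name in ("sigma", "ridge_lambda", "epsilon", "cost_C"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} candidates must be non-empty")
            if name != "epsilon" and any(v <= 0 for v in vals):
                raise ValueError(f"{name} candidates must be positive")
            if name == "epsilon" and any(v < 0 for v in vals):
                raise ValueError("epsilon candidates must be >= 0")


@dataclass(frozen=True)
class GridSearchResult:
    best_params: dict
    best_error: float
    table: pd.DataFrame


def _rkhs_cv_errors(
    K: np.ndarray,
    Y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    ridge_lambda: float,
) -> np.ndarray:
    """Pooled held-out 3-D errors for one (precomputed kernel, lambda) cell."""
    errors = []
    for train, test in folds:
        ys = Standardizer.fit(Y[train])
        Ys = ys.transform(Y[train])
        alpha = _solve_kernel_ridge(K[np.ix_(train, train)], Ys, ridge_lambda)
        pred = ys.inverse(K[np.ix_(test, train)] @ alpha)
        errors.append(np.linalg.norm(pred - Y[test], axis=1))
    return np.concatenate(errors)


def _svr_cv_errors(
    K: np.ndarray,
    Y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    epsilon: float,
    C: float,
    tol: float,
) -> np.ndarray:
    """Pooled held-out 3-D errors for one (precomputed kernel, epsilon, C) cell.

    Model selection only: the precomputed Gram matrix and a bounded SMO
    budget are enough to rank cells; the winning cell is refit exactly.
    """
    from sklearn.svm import SVR as _SVR

    errors = []
    for train, test in folds:
        preds = []
        for j in range(Y.shape[1]):
            ys = Standardizer.fit(Y[train, j][:, None])
            svr = _SVR(kernel="precomputed", C=C, epsilon=epsilon, tol=tol,
                       cache_size=64, max_iter=20_000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                svr.fit(K[np.ix_(train, train)], ys.transform(Y[train, j][:, None])[:, 0])
            raw = svr.predict(K[np.ix_(test, train)])
            preds.append(ys.inverse(raw[:, None])[:, 0])
        pred = np.column_stack(preds)
        errors.append(np.linalg.norm(pred - Y[test], axis=1))
    return np.concatenate(errors)


def grid_search(
    X: Sequence,
    Y: Sequence,
    groups: Sequence,
    kind: str = "rkhs",
    grid: HyperparamGrid | None = None,
    n_splits: int | None = None,
    svr_tol: float = 1e-3,
) -> GridSearchResult:
    """Exhaustive hyperparameter search scored by grouped-CV mean 3-D error.

    Ties are broken toward maximal regularization: larger lambda, then larger
    epsilon, smaller C, larger sigma.  Features are standardized once over
    the search data so Gaussian kernels can be shared across folds; the
    returned parameters are applied to models that re-standardize on their
    own training sets.
    """
    grid = grid or HyperparamGrid()
    X = _as_2d(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = np.asarray(groups)
    if len(set(groups.tolist())) < 2:
        raise ValueError("grid search needs at least 2 groups")
    folds = grouped_folds(groups, n_splits)
    Xs = Standardizer.fit(X).transform(X)

    rows: list[dict] = []
    d2 = cdist(Xs, Xs, "sqeuclidean")
    if kind == "rkhs":
        for sigma in grid.sigma:
            K = np.exp(-d2 / (2.0 * sigma**2))
            for lam in grid.ridge_lambda:
                errs = _rkhs_cv_errors(K, Y, folds, lam)
                rows.append(
                    {"sigma": sigma, "ridge_lambda": lam,
                     "mean_error_mm": float(errs.mean()),
                     "sd_error_mm": float(errs.std(ddof=1))}
                )
        param_names = ["sigma", "ridge_lambda"]
        # ties broken toward maximal regularization: larger lambda, larger sigma
        preference = lambda r: (r["mean_error_mm"], -r["ridge_lambda"], -r["sigma"])
    elif kind == "svr":
        for sigma in grid.sigma:
            K = np.exp(-d2 / (2.0 * sigma**2))
            for eps in grid.epsilon:
                for C in grid.cost_C:
                    errs = _svr_cv_errors(K, Y, folds, eps, C, svr_tol)
                    rows.append(
                        {"sigma": sigma, "epsilon": eps, "C": C,
                         "mean_error_mm": float(errs.mean()),
                         "sd_error_mm": float(errs.std(ddof=1))}
                    )
        param_names = ["sigma", "epsilon", "C"]
        # larger epsilon, then smaller C, then larger sigma
        preference = lambda r: (r["mean_error_mm"], -r["epsilon"], r["C"], -r["sigma"])
    else:
        raise ValueError(f"unknown model kind for grid search: {kind!r}")

    best = min(rows, key=preference)
    return GridSearchResult(
        best_params={k: float(best[k]) for k in param_names},
        best_error=float(best["mean_error_mm"]),
        table=pd.DataFrame(rows),
    )


def greedy_feature_selection_rkhs(
    X: Sequence,
    Y: Sequence,
    groups: Sequence,
    sigma_scale: float = 1.0,
    ridge_lambda: float = 1e-3,
    improvement_threshold: float = 0.01,
    max_features: int | None = None,
    n_splits: int | None = None,
) -> tuple[list[int], list[float]]:
    """Greedy forward feature selection for the kernel-ridge metamodel.

    Starting from the empty set, repeatedly adds the feature whose inclusion
    most reduces the grouped-CV mean 3-D error; stops when the best addition
    improves the error by less than ``improvement_threshold`` (relative).
    The kernel width adapts to the subset size as ``sigma_scale * sqrt(k)``.
    Returns the ordered selection and the error trace (entry 0 is the
    no-feature baseline: the grand-mean predictor).  Ties prefer the lowest
    feature index.
    """
    X = _as_2d(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    folds = grouped_folds(np.asarray(groups), n_splits)
    Xs = Standardizer.fit(X).transform(X)

    def cv_error(cols: list[int]) -> float:
        if not cols:
            errs = []
            for train, test in folds:
                center = Y[train].mean(axis=0)
                errs.append(np.linalg.norm(Y[test] - center, axis=1))
            return float(np.concatenate(errs).mean())
        sub = Xs[:, cols]
        K = kernel_matrix(sub, sub, sigma_scale * np.sqrt(len(cols)))
        return float(_rkhs_cv_errors(K, Y, folds, ridge_lambda).mean())

    selected: list[int] = []
    trace = [cv_error(selected)]
    limit = max_features or X.shape[1]
    remaining = list(range(X.shape[1]))
    while len(selected) < limit and remaining:
        best_feat, best_err = None, None
        for f in remaining:  # ascending index order -> first index wins ties
            err = cv_error(selected + [f])
            if best_err is None or err < best_err:
                best_feat, best_err = f, err
        if best_err >= trace[-1] * (1.0 - improvement_threshold):
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        trace.append(best_err)
    return selected, trace
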