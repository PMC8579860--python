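"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they verify: the kernel-ridge
oracle minimises the regression objective numerically instead of solving
the normal equations; the SVR oracle solves the dense dual quadratic
program with a generic NLP solver instead of SMO; the line-distance oracle
scans the lead axis instead of using the cross product.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial.distance import cdist


def rbf_gram(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-cdist(np.atleast_2d(A), np.atleast_2d(B), "sqeuclidean")
                  / (2.0 * sigma**2))


def kernel_ridge_numeric(K: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Minimise (1/n)||K a - y||^2 + lam a'Ka by BFGS from a = 0."""
    n = len(y)

    def objective(a):
        r = K @ a - y
        return r @ r / n + lam * a @ K @ a

    def grad(a):
        return 2.0 / n * K @ (K @ a - y) + 2.0 * lam * K @ a

    res = minimize(objective, np.zeros(n), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 10_000})
    return res.x


def svr_dual_qp(K: np.ndarray, y: np.ndarray, epsilon: float, C: float):
    """Solve the epsilon-SVR dual with a dense generic QP (SLSQP).

    Variables are beta = (alpha, alpha_star) stacked; returns
    (dual = alpha - alpha_star, bias).  The bias comes from the KKT
    condition at a free support vector, with a convex 1-D fallback when no
    strictly-free vector exists.
    """
    n = len(y)

    def objective(beta):
        d = beta[:n] - beta[n:]
        return 0.5 * d @ K @ d + epsilon * beta.sum() - y @ d

    def grad(beta):
        d = beta[:n] - beta[n:]
        g = K @ d
        return np.concatenate([g + epsilon - y, -g + epsilon + y])

    constraints = [{"type": "eq",
                    "fun": lambda b: np.sum(b[:n] - b[n:]),
                    "jac": lambda b: np.concatenate([np.ones(n), -np.ones(n)])}]
    res = minimize(objective, np.zeros(2 * n), jac=grad, method="SLSQP",
                   bounds=[(0.0, C)] * (2 * n), constraints=constraints,
                   options={"ftol": 1e-14, "maxiter": 2000})
    beta = res.x
    dual = beta[:n] - beta[n:]
    g = K @ dual

    # bias via KKT at free support vectors
    free_tol = 1e-7 * C
    b_vals = []
    for i in range(n):
        if free_tol < beta[i] < C - free_tol:  # alpha free: y - f = eps
            b_vals.append(y[i] - epsilon - g[i])
        if free_tol < beta[n + i] < C - free_tol:  # alpha* free: f - y = eps
            b_vals.append(y[i] + epsilon - g[i])
    if b_vals:
        bias = float(np.mean(b_vals))
    else:
        # minimise the primal slack cost over b (convex piecewise linear)
        def slack_cost(b):
            return np.maximum(np.abs(y - g - b) - epsilon, 0.0).sum()

        lo, hi = float(np.min(y - g)) - epsilon, float(np.max(y - g)) + epsilon
        bias = float(minimize_scalar(slack_cost, bounds=(lo, hi), method="bounded").x)
    return dual, bias


def svr_predict(Xq, X, dual, bias, sigma):
    return rbf_gram(Xq, X, sigma) @ dual + bias


def line_distance_scan(L: np.ndarray, u: np.ndarray, T: np.ndarray,
                       n_points: int = 100_000, span: float = 100.0) -> float:
    """Minimum distance from T to the line L + s u by dense sampling of s."""
    s = np.linspace(-span, span, n_points)
    pts = L[None, :] + s[:, None] * (u / np.linalg.norm(u))[None, :]
    return float(np.linalg.norm(pts - T[None, :], axis=1).min())
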