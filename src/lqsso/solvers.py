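"""Penalized least-squares solvers: lasso, weighted lasso, lqsso, adaptive lasso.

All fitting happens on standardized data (columns centered with second moment
``sum x^2 / n = 1``, response centered) and minimizes the un-normalized
objective

    ||y - X beta||^2 + lam * sum_j f_j |beta_j|,

where ``f_j`` are penalty factors (all ones for the lasso).  Weighted
problems are reduced to a plain lasso by the column-rescaling identity:
divide column j by f_j, solve the lasso, divide the solution by f_j.  Users
of solvers on the conventional per-observation scale (glmnet, scikit-learn:
(1/2n)RSS + alpha * pen) can convert via ``lam = 2 * n * alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from ._cd import cd_path, cd_solve
from .penalty import EPS_WEIGHT, InitialEstimates, compute_weights

__all__ = [
    "RegressionData",
    "FitResult",
    "KKTReport",
    "standardize",
    "lasso_cd",
    "weighted_lasso",
    "weighted_lasso_path",
    "fit_lqsso",
    "fit_adaptive_lasso",
    "ols_init",
    "ridge_init",
    "kkt_check",
]

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100_000


@dataclass(frozen=True)
class ScalingInfo:
    x_mean: NDArray[np.float64]
    x_scale: NDArray[np.float64]
    y_mean: float


@dataclass(frozen=True)
class RegressionData:
    """Standardized design and centered response.

    Columns of ``X`` have mean zero and second moment sum(x^2)/n = 1; ``y``
    has mean zero.  ``scaling`` retains the original column means/scales and
    response mean so fits can be mapped back to the raw scale.
    """

    X: NDArray[np.float64]
    y: NDArray[np.float64]
    scaling: ScalingInfo

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def standardize(X_raw: ArrayLike, y_raw: ArrayLike) -> RegressionData:
    """Center and scale a raw design matrix and response.

    Each column is centered and divided by its root mean square so that
    sum_i x_ij^2 / n = 1; the response is centered.  Constant columns are
    rejected (the rescaling would divide by zero).
    """
    X = np.ascontiguousarray(X_raw, dtype=float)
    y = np.asarray(y_raw, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} entries")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    x_scale = np.sqrt(np.mean(Xc**2, axis=0))
    zero = np.flatnonzero(x_scale <= 0)
    if zero.size:
        raise ValueError(f"constant column(s) at index {zero.tolist()}; "
                         "remove them before fitting")
    y_mean = float(y.mean())
    return RegressionData(
        X=np.ascontiguousarray(Xc / x_scale),
        y=y - y_mean,
        scaling=ScalingInfo(x_mean=x_mean, x_scale=x_scale, y_mean=y_mean),
    )


@dataclass(frozen=True)
class FitResult:
    """A fitted penalized regression on the standardized scale."""

    method: str
    beta: NDArray[np.float64]
    lam: float
    penalty_factors: NDArray[np.float64]
    objective: float
    n_iter: int
    converged: bool
    tau: float | None = None
    gamma: float | None = None
    q: float = 1.0
    init_source: str | None = None
    beta_original: NDArray[np.float64] | None = None
    intercept: float | None = None
    objective_trace: NDArray[np.float64] | None = None

    @property
    def active_set(self) -> NDArray[np.int64]:
        return np.flatnonzero(self.beta != 0.0)

    def predict(self, X_raw: ArrayLike) -> NDArray[np.float64]:
        """Predict the response for raw-scale inputs."""
        X = np.asarray(X_raw, dtype=float)
        return self.intercept + X @ self.beta_original


def _objective(X, y, beta, lam, factors) -> float:
    r = y - X @ beta
    return float(r @ r + lam * np.sum(factors * np.abs(beta)))


def _finalize(method, data, beta, lam, factors, n_iter, converged, *,
              tau=None, gamma=None, q=1.0, init_source=None, trace=None):
    sc = data.scaling
    beta_orig = beta / sc.x_scale
    intercept = sc.y_mean - float(beta_orig @ sc.x_mean)
    return FitResult(
        method=method,
        beta=beta,
        lam=float(lam),
        penalty_factors=factors,
        objective=_objective(data.X, data.y, beta, lam, factors),
        n_iter=int(n_iter),
        converged=bool(converged),
        tau=tau,
        gamma=gamma,
        q=q,
        init_source=init_source,
        beta_original=beta_orig,
        intercept=intercept,
        objective_trace=trace,
    )


def _solve_rescaled(X, y, lam, factors, tol, max_iter, track_objective):
    """Solve the weighted problem via the column-rescaling identity."""
    Xw = np.ascontiguousarray(X / factors)
    beta_w = np.zeros(X.shape[1])
    trace = None
    if track_objective:
        vals = []
        total = 0
        converged = False
        while total < max_iter:
            it, ok, _ = cd_solve(Xw, y, lam, beta_w, tol, 1)
            total += 1
            vals.append(_objective(Xw, y, beta_w, lam, np.ones_like(factors)))
            if ok:
                converged = True
                break
        n_iter = total
        trace = np.asarray(vals)
    else:
        n_iter, converged, _ = cd_solve(Xw, y, lam, beta_w, tol, max_iter)
    return beta_w / factors, n_iter, converged, trace


def _factors(weights, q, normalize) -> NDArray[np.float64]:
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be strictly positive and finite")
    f = w**q
    if normalize:
        f = f / f.mean()
    return f


def lasso_cd(
    data: RegressionData,
    lam: float,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    track_objective: bool = False,
) -> FitResult:
    """Lasso fit by cyclic coordinate descent (soft-thresholding updates)."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    factors = np.ones(data.p)
    beta, n_iter, conv, trace = _solve_rescaled(
        data.X, data.y, lam, factors, tol, max_iter, track_objective)
    return _finalize("lasso", data, beta, lam, factors, n_iter, conv, trace=trace)


def weighted_lasso(
    data: RegressionData,
    lam: float,
    weights: ArrayLike,
    q: float = 1.0,
    *,
    normalize: bool = False,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    track_objective: bool = False,
) -> FitResult:
    """Weighted lasso: minimize RSS + lam * sum_j w_j**q |beta_j|.

    Implemented by the three-step reduction: rescale column j by 1/w_j**q,
    solve the plain lasso at ``lam``, divide the solution back by w_j**q.
    With ``normalize=True`` the penalty factors w_j**q are first scaled to
    mean one (the convention of glmnet's penalty.factor), which makes the
    overall shrinkage level comparable across weight vectors.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    factors = _factors(weights, q, normalize)
    if factors.shape[0] != data.p:
        raise ValueError("weights length does not match number of predictors")
    beta, n_iter, conv, trace = _solve_rescaled(
        data.X, data.y, lam, factors, tol, max_iter, track_objective)
    return _finalize("weighted_lasso", data, beta, lam, factors, n_iter, conv,
                     q=q, trace=trace)


def weighted_lasso_path(
    data: RegressionData,
    lams: ArrayLike,
    weights: ArrayLike | None = None,
    q: float = 1.0,
    *,
    normalize: bool = False,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[NDArray[np.float64], NDArray[np.bool_]]:
    """Warm-started solutions over a lambda grid (any order).

    Returns (betas, converged) with one row per requested lambda, in the
    requested order; internally solved from the largest lambda down.
    """
    lams = np.asarray(lams, dtype=float)
    if np.any(lams < 0):
        raise ValueError("lambda values must be nonnegative")
    factors = (np.ones(data.p) if weights is None
               else _factors(weights, q, normalize))
    Xw = np.ascontiguousarray(data.X / factors)
    order = np.argsort(-lams)
    betas_w, _, conv = cd_path(Xw, data.y, lams[order], tol, max_iter)
    betas = np.empty_like(betas_w)
    conv_out = np.empty_like(conv)
    betas[order] = betas_w / factors
    conv_out[order] = conv
    return betas, conv_out


def fit_lqsso(
    data: RegressionData,
    lam: float,
    tau: float,
    init: InitialEstimates | None = None,
    q: float = 1.0,
    *,
    normalize: bool = False,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Lqsso fit: weighted lasso with check-function weights tau / (1 - tau).

    ``init`` defaults to OLS estimates when p < n and ridge estimates
    otherwise, matching the recommended initialization.
    """
    if init is None:
        init = ols_init(data) if data.p < data.n else ridge_init(data)
    weights = compute_weights(init, tau)
    fit = weighted_lasso(data, lam, weights, q, normalize=normalize,
                         tol=tol, max_iter=max_iter)
    return FitResult(
        method="lqsso", beta=fit.beta, lam=fit.lam,
        penalty_factors=fit.penalty_factors, objective=fit.objective,
        n_iter=fit.n_iter, converged=fit.converged, tau=float(tau), q=q,
        init_source=init.source, beta_original=fit.beta_original,
        intercept=fit.intercept,
    )


def fit_adaptive_lasso(
    data: RegressionData,
    lam: float,
    gamma: float,
    init: InitialEstimates | None = None,
    *,
    normalize: bool = False,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Adaptive lasso: weighted lasso with weights 1 / |beta_init|**gamma.

    Near-zero initial estimates get their weight clamped above at
    1 / EPS_WEIGHT so the problem stays well posed.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if init is None:
        init = ols_init(data) if data.p < data.n else ridge_init(data)
    if np.all(init.beta == 0):
        raise ValueError("all initial estimates are zero; adaptive weights "
                         "are undefined")
    weights = 1.0 / np.maximum(np.abs(init.beta), EPS_WEIGHT) ** gamma
    weights = np.minimum(weights, 1.0 / EPS_WEIGHT)
    fit = weighted_lasso(data, lam, weights, q=1.0, normalize=normalize,
                         tol=tol, max_iter=max_iter)
    return FitResult(
        method="alasso", beta=fit.beta, lam=fit.lam,
        penalty_factors=fit.penalty_factors, objective=fit.objective,
        n_iter=fit.n_iter, converged=fit.converged, gamma=float(gamma),
        init_source=init.source, beta_original=fit.beta_original,
        intercept=fit.intercept,
    )


def ols_init(data: RegressionData) -> InitialEstimates:
    """Ordinary least squares initial estimates (requires p < n, full rank)."""
    if data.p >= data.n:
        raise ValueError("OLS initialization requires p < n; use ridge_init "
                         "in the high-dimensional case")
    gram = data.X.T @ data.X
    try:
        c, low = _cho_factor(gram)
        beta = _cho_solve((c, low), data.X.T @ data.y)
    except np.linalg.LinAlgError:
        raise ValueError("X'X is singular; use ridge_init instead") from None
    return InitialEstimates(beta=beta, source="ols")


def ridge_init(
    data: RegressionData,
    ridge_lambda: float | None = None,
) -> InitialEstimates:
    """Ridge initial estimates (X'X + lambda I)^(-1) X'y.

    When ``ridge_lambda`` is not given it is chosen by efficient leave-one-out
    cross-validation over a wide logarithmic grid.
    """
    if ridge_lambda is None:
        from sklearn.linear_model import RidgeCV

        model = RidgeCV(alphas=np.logspace(-2, 4, 25), fit_intercept=False)
        model.fit(data.X, data.y)
        beta = model.coef_
    else:
        if ridge_lambda <= 0:
            raise ValueError("ridge_lambda must be positive")
        gram = data.X.T @ data.X + ridge_lambda * np.eye(data.p)
        beta = np.linalg.solve(gram, data.X.T @ data.y)
    return InitialEstimates(beta=beta, source="ridge")


def _cho_factor(a):
    from scipy.linalg import cho_factor

    return cho_factor(a)


def _cho_solve(cf, b):
    from scipy.linalg import cho_solve

    return cho_solve(cf, b)


@dataclass(frozen=True)
class KKTReport:
    """Stationarity diagnostics for a penalized least-squares solution.

    For active coordinates 2 x_j'(y - X beta) must equal lam * f_j * sign
    (beta_j); for inactive ones its magnitude must not exceed lam * f_j.
    """

    passed: bool
    worst_active: float
    worst_inactive: float
    active_violations: NDArray[np.int64]
    inactive_violations: NDArray[np.int64]
    tol: float


def kkt_check(
    data: RegressionData,
    fit: FitResult,
    tol: float = 1e-6,
) -> KKTReport:
    """Verify the first-order optimality conditions of a fit."""
    grad = 2.0 * data.X.T @ (data.y - data.X @ fit.beta)
    lam_f = fit.lam * fit.penalty_factors
    active = fit.beta != 0.0
    act_gap = np.abs(grad[active] - lam_f[active] * np.sign(fit.beta[active]))
    inact_gap = np.abs(grad[~active]) - lam_f[~active]
    worst_active = float(act_gap.max()) if act_gap.size else 0.0
    worst_inactive = float(inact_gap.max()) if inact_gap.size else 0.0
    act_idx = np.flatnonzero(active)
    inact_idx = np.flatnonzero(~active)
    return KKTReport(
        passed=worst_active <= tol and worst_inactive <= tol,
        worst_active=worst_active,
        worst_inactive=worst_inactive,
        active_violations=act_idx[act_gap > tol] if act_gap.size else act_idx[:0],
        inactive_violations=(inact_idx[inact_gap > tol]
                             if inact_gap.size else inact_idx[:0]),
        tol=tol,
    )
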