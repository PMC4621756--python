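"""Elastic-net / lasso regression by cyclic coordinate descent.

The objective, in the glmnet parameterization the field uses for drug
sensitivity modeling, is

    (1/2n) * sum_i (y_i - b0 - x_i' b)^2
        + lam * ( alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 )

with alpha in [0, 1] the L1/L2 mixing weight (alpha = 1 is the lasso) and
lam >= 0 the penalty amplitude.  Predictors are standardized internally
(ddof=0) and the response centered; coefficients are reported on the
original predictor scale and the intercept is unpenalized.

Coordinate descent runs on the Gram matrix (covariance updates), compiled
with numba; this keeps the leave-pair-out cross-validation workload — tens
of thousands of regularization-path fits — tractable.

Model selection follows the study design: for each alpha on a grid, the best
lam is picked by K-fold cross-validation on mean squared error; because the
MSE-vs-alpha curve is unstable from run to run, the minimum MSE is averaged
over repeated CV runs and the alpha with the lowest average is chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from ._seeds import derive_seed


class ConvergenceWarning(UserWarning):
    """Coordinate descent stopped at max_iter without meeting tol."""


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


def lambda_max(X, y, alpha: float) -> float:
    """Smallest lam at which the elastic-net solution is all-zero.

    Assumes X column-standardized and y centered: max_j |<x_j, y>| / (n*alpha).
    """
    if alpha <= 0:
        raise ValueError("lambda_max is undefined for alpha <= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    return float(np.max(np.abs(X.T @ y)) / (n * alpha))


@numba.njit(cache=True)
def _cd_sweep_once(X, r, beta, gdiag, n, l1, l2, active_only):  # pragma: no cover
    """One cyclic sweep with residual updates; returns max coefficient change.

    X is the standardized design, r the current residual (updated in place),
    gdiag[j] = <x_j, x_j>/n.  ``active_only`` restricts the sweep to the
    current nonzero set.
    """
    p = X.shape[1]
    max_d = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        gjj = gdiag[j]
        if gjj <= 0.0:
            beta[j] = 0.0
            continue
        rho = 0.0
        for i in range(X.shape[0]):
            rho += X[i, j] * r[i]
        rho = rho / n + gjj * bj
        if rho > l1:
            bn = (rho - l1) / (gjj + l2)
        elif rho < -l1:
            bn = (rho + l1) / (gjj + l2)
        else:
            bn = 0.0
        d = bn - bj
        if d != 0.0:
            beta[j] = bn
            for i in range(X.shape[0]):
                r[i] -= d * X[i, j]
            ad = abs(d)
            if ad > max_d:
                max_d = ad
    return max_d


@numba.njit(cache=True)
def _cd_solve(X, r, beta, gdiag, n, l1, l2, tol, max_iter):  # pragma: no cover
    """Full-sweep / active-set coordinate descent until max change < tol."""
    total = 0
    while total < max_iter:
        max_d = _cd_sweep_once(X, r, beta, gdiag, n, l1, l2, False)
        total += 1
        if max_d < tol:
            return total, True
        while total < max_iter:
            max_d = _cd_sweep_once(X, r, beta, gdiag, n, l1, l2, True)
            total += 1
            if max_d < tol:
                break
    return total, False


@numba.njit(cache=True)
def _cd_path_kernel(X, yc, gdiag, grid, alpha, tol, max_iter):  # pragma: no cover
    """Warm-started coordinate descent along a decreasing lam grid.

    Returns (B, sweeps, converged) with B[l] the standardized-scale solution
    at grid[l]."""
    n, p = X.shape
    L = grid.shape[0]
    B = np.zeros((L, p))
    sweeps = np.zeros(L, dtype=np.int64)
    converged = np.ones(L, dtype=np.bool_)
    beta = np.zeros(p)
    r = yc.copy()
    for l in range(L):
        l1 = grid[l] * alpha
        l2 = grid[l] * (1.0 - alpha)
        n_iter, ok = _cd_solve(X, r, beta, gdiag, n, l1, l2, tol, max_iter)
        sweeps[l] = n_iter
        converged[l] = ok
        B[l] = beta
    return B, sweeps, converged


def _prepare(Xv: np.ndarray, yv: np.ndarray):
    """Standardize columns (Fortran order for the kernel), center y."""
    std = _Standardizer(Xv)
    Xs = std.transform(Xv)
    Xs[:, ~std.active] = 0.0
    Xs = np.asfortranarray(Xs)
    ymean = yv.mean()
    yc = yv - ymean
    gdiag = np.einsum("ij,ij->j", Xs, Xs) / Xv.shape[0]
    return std, Xs, ymean, yc, gdiag


def _path_matrix(Xv, yv, alpha, grid, tol, max_iter):
    """Original-scale coefficients/intercepts along a lam grid (fast route)."""
    std, Xs, ymean, yc, gdiag = _prepare(Xv, yv)
    B, sweeps, converged = _cd_path_kernel(
        Xs, yc, gdiag, np.asarray(grid, dtype=float), alpha, tol, max_iter
    )
    coefs = np.where(std.active[None, :], B / std.sd_safe[None, :], 0.0)
    intercepts = ymean - coefs @ std.mean
    return coefs, intercepts, sweeps, converged


def _gram_objective(G, c, yty_n, beta, l1, l2) -> float:
    """Penalized objective evaluated via the Gram matrix."""
    quad = 0.5 * (yty_n - 2.0 * c @ beta + beta @ (G @ beta))
    return float(quad + l1 * np.sum(np.abs(beta)) + 0.5 * l2 * np.sum(beta**2))


@dataclass
class ElasticNetModel:
    """One fitted penalized model on the original predictor scale."""

    alpha: float
    lam: float
    intercept: float
    coefficients: dict[str, float]          # nonzero coefficients only
    n_nonzero: int
    converged: bool = True
    n_iter: int = 0
    feature_ids: list[str] = field(default_factory=list)
    _coef_vector: np.ndarray | None = None  # dense, aligned with feature_ids

    def coef_array(self) -> np.ndarray:
        if self._coef_vector is not None:
            return self._coef_vector
        return np.array([self.coefficients.get(f, 0.0) for f in self.feature_ids])

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coef_array()

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "lambda": self.lam,
            "intercept": self.intercept,
            "coefficients": {k: v for k, v in sorted(self.coefficients.items())},
        }


class _Standardizer:
    """Column standardization (ddof=0) with zero-variance columns frozen out."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.active = self.sd > 0
        self.sd_safe = np.where(self.active, self.sd, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd_safe


def _feature_ids(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"x{j}" for j in range(np.asarray(X).shape[1])]


def enet_fit(
    X,
    y,
    alpha: float,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    warm_beta: np.ndarray | None = None,
    check_objective: bool = False,
) -> ElasticNetModel:
    """Fit one elastic-net model at fixed (alpha, lam).

    ``warm_beta`` (standardized scale) warm-starts the solver; with
    ``check_objective`` the penalized objective is verified to be
    non-increasing across sweeps.
    """
    ids = _feature_ids(X)
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xv.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if yv.shape[0] != n:
        raise ValueError("X and y are misaligned")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if np.isnan(Xv).any() or np.isnan(yv).any():
        raise ValueError("missing values are not supported")

    std, Xs, ymean, yc, gdiag = _prepare(Xv, yv)
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)

    beta = np.zeros(p) if warm_beta is None else np.array(warm_beta, dtype=float)
    r = yc - Xs @ beta

    if check_objective:
        G = (Xs.T @ Xs) / n
        c = (Xs.T @ yc) / n
        yty_n = float(yc @ yc) / n
        obj = _gram_objective(G, c, yty_n, beta, l1, l2)
        total, converged = 0, False
        while total < max_iter and not converged:
            # one full sweep at a time, verifying monotone descent
            sweeps, converged = _cd_solve(Xs, r, beta, gdiag, n, l1, l2, tol, 1)
            total += sweeps
            new_obj = _gram_objective(G, c, yty_n, beta, l1, l2)
            if new_obj > obj + 1e-10 * max(1.0, abs(obj)):
                raise AssertionError("objective increased across a coordinate-descent sweep")
            obj = new_obj
        n_iter = total
    else:
        n_iter, converged = _cd_solve(Xs, r, beta, gdiag, n, l1, l2, tol, max_iter)

    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_iter} sweeps", ConvergenceWarning
        )

    coef = np.where(std.active, beta / std.sd_safe, 0.0)
    intercept = ymean - float(std.mean @ coef)
    nonzero = {ids[j]: float(coef[j]) for j in np.flatnonzero(coef)}
    return ElasticNetModel(
        alpha=float(alpha),
        lam=float(lam),
        intercept=float(intercept),
        coefficients=nonzero,
        n_nonzero=len(nonzero),
        converged=converged,
        n_iter=n_iter,
        feature_ids=ids,
        _coef_vector=coef,
    )


def kkt_violation(X, y, model: ElasticNetModel) -> float:
    """Max KKT stationarity violation of a fitted model (standardized scale).

    For each coordinate j the subgradient condition is
    |<x_j, r>/n - lam*(1-alpha)*b_j| <= lam*alpha, with equality and matching
    sign when b_j != 0.  Returns the largest excess over the bound.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xv.shape[0]
    std = _Standardizer(Xv)
    Xs = std.transform(Xv)
    Xs[:, ~std.active] = 0.0
    beta_std = model.coef_array() * std.sd_safe
    yc = yv - yv.mean()
    r = yc - Xs @ beta_std
    grad = Xs.T @ r / n - model.lam * (1.0 - model.alpha) * beta_std
    bound = model.lam * model.alpha
    viol = np.abs(grad) - bound
    nz = beta_std != 0
    # active coordinates must sit exactly on the boundary with the right sign
    viol[nz] = np.abs(grad[nz] - bound * np.sign(beta_std[nz]))
    return float(np.max(viol)) if viol.size else 0.0


def lambda_grid(X, y, alpha: float, n_lambda: int = 100, lambda_min_ratio: float = 0.01):
    """Geometric lam grid from lambda_max down to lambda_max * ratio."""
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    std = _Standardizer(Xv)
    Xs = std.transform(Xv)
    Xs[:, ~std.active] = 0.0
    lmax = lambda_max(Xs, yv - yv.mean(), alpha)
    if lmax <= 0:
        lmax = 1e-3
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


def fit_path(
    X,
    y,
    alpha: float,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    lam_values=None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> list[ElasticNetModel]:
    """Warm-started fits along a decreasing lam grid.

    The standardized design is prepared once and reused across the whole
    grid, so a full path costs little more than a single fit.
    """
    if alpha <= 0 and lam_values is None:
        raise ValueError("alpha must be > 0 for automatic grid construction")
    ids = _feature_ids(X)
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()

    std, Xs, ymean, yc, gdiag = _prepare(Xv, yv)

    if lam_values is not None:
        grid = np.asarray(lam_values, dtype=float)
    else:
        lmax = lambda_max(Xs, yc, alpha)
        if lmax <= 0:
            lmax = 1e-3
        grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)

    B, sweeps, converged = _cd_path_kernel(Xs, yc, gdiag, grid, alpha, tol, max_iter)
    models: list[ElasticNetModel] = []
    for k, lam in enumerate(grid):
        coef = np.where(std.active, B[k] / std.sd_safe, 0.0)
        intercept = ymean - float(std.mean @ coef)
        nz_idx = np.flatnonzero(coef)
        models.append(
            ElasticNetModel(
                alpha=float(alpha),
                lam=float(lam),
                intercept=intercept,
                coefficients={ids[j]: float(coef[j]) for j in nz_idx},
                n_nonzero=len(nz_idx),
                converged=bool(converged[k]),
                n_iter=int(sweeps[k]),
                feature_ids=ids,
                _coef_vector=coef,
            )
        )
    if not converged.all():
        warnings.warn("some path fits did not converge", ConvergenceWarning)
    return models


@dataclass
class CVCurve:
    """Cross-validated MSE along the lam path at one alpha."""

    alpha: float
    lambda_grid: np.ndarray
    mean_mse: np.ndarray
    se_mse: np.ndarray
    lambda_min: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.lambda_grid) < 0):
            raise ValueError("lambda_grid must be strictly decreasing")
        if len(self.mean_mse) != len(self.lambda_grid):
            raise ValueError("mean_mse length mismatch")


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced random fold labels (sizes differ by at most one)."""
    labels = np.arange(n) % n_folds
    return labels[rng.permutation(n)]


def cv_lambda(
    X,
    y,
    alpha: float,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> CVCurve:
    """K-fold cross-validation of the lam path at a fixed alpha.

    The grid is built from the full data; each fold refits the path on its
    training portion and scores held-out squared error on the common grid.
    lambda_min is the grid value minimizing the fold-averaged MSE (the
    largest lam on ties, i.e. the sparser model).
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xv.shape[0]
    if not (2 <= n_folds <= n):
        raise ValueError("n_folds must be between 2 and n")

    grid = lambda_grid(X, y, alpha, n_lambda, lambda_min_ratio)
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n, n_folds, rng)

    fold_mse = np.empty((n_folds, len(grid)))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        coefs, intercepts, _, _ = _path_matrix(
            Xv[train], yv[train], alpha, grid, tol, max_iter
        )
        preds = Xv[test] @ coefs.T + intercepts[None, :]   # n_test x L
        fold_mse[f] = np.mean((yv[test, None] - preds) ** 2, axis=0)

    mean_mse = fold_mse.mean(axis=0)
    se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
    lambda_min = float(grid[int(np.argmin(mean_mse))])  # first index = largest lam
    return CVCurve(float(alpha), grid, mean_mse, se_mse, lambda_min)


DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


def select_alpha(
    X,
    y,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    **cv_kwargs,
) -> tuple[float, np.ndarray]:
    """Pick the mixing weight by averaged repeated cross-validation.

    For each alpha, ``n_repeats`` CV runs (fold assignments shared across
    alphas within a repeat, re-randomized between repeats) record the
    minimum mean MSE on the lam path; the alpha minimizing the
    repeat-averaged minimum wins, with ties resolved toward the smaller
    alpha.  Returns (best_alpha, averaged minima aligned with alpha_grid).
    """
    grid = sorted(float(a) for a in alpha_grid)
    if not grid:
        raise ValueError("alpha_grid must be non-empty")
    if any(a <= 0 or a > 1 for a in grid):
        raise ValueError("alpha values must be in (0, 1]")

    minima = np.zeros((len(grid), n_repeats))
    for r in range(n_repeats):
        run_seed = derive_seed(seed, "cv-repeat", r)
        for i, a in enumerate(grid):
            curve = cv_lambda(X, y, a, n_folds=n_folds, seed=run_seed, **cv_kwargs)
            minima[i, r] = curve.mean_mse.min()
    avg = minima.mean(axis=1)
    best = grid[int(np.argmin(avg))]  # first occurrence = smallest alpha
    return float(best), avg


class _BaseEstimator:
    """Minimal scikit-learn-compatible parameter handling."""

    @classmethod
    def _param_names(cls) -> list[str]:
        import inspect

        sig = inspect.signature(cls.__init__)
        return [p for p in sig.parameters if p != "self"]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params):
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r} for {type(self).__name__}")
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"


class ElasticNet(_BaseEstimator):
    """Elastic-net regression estimator at fixed (alpha, lam).

    Parameters
    ----------
    alpha : L1/L2 mixing weight in [0, 1] (1 = lasso).
    lam : penalty amplitude (lambda), >= 0.
    tol, max_iter : coordinate-descent stopping rule (max coefficient change
        on the standardized scale).
    check_objective : verify monotone objective decrease each sweep.
    """

    def __init__(self, alpha=1.0, lam=1.0, tol=1e-7, max_iter=100_000, check_objective=False):
        self.alpha = alpha
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter
        self.check_objective = check_objective

    def fit(self, X, y):
        model = enet_fit(
            X,
            y,
            self.alpha,
            self.lam,
            tol=self.tol,
            max_iter=self.max_iter,
            check_objective=self.check_objective,
        )
        self.model_ = model
        self.coef_ = model.coef_array()
        self.intercept_ = model.intercept
        self.n_iter_ = model.n_iter
        self.feature_ids_ = list(model.feature_ids)
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_


class ElasticNetCV(_BaseEstimator):
    """Elastic net with the study's alpha-grid / lam selection procedure.

    fit() selects alpha by ``n_repeats``-averaged K-fold CV minima over
    ``alpha_grid``, then lam by a final CV run at the winning alpha, and
    refits on all data.  Fitted attributes: ``alpha_``, ``lam_``, ``coef_``,
    ``intercept_``, ``alpha_mse_``, ``cv_curve_``, ``model_``.
    """

    def __init__(
        self,
        alpha_grid=DEFAULT_ALPHA_GRID,
        n_repeats=10,
        n_folds=10,
        n_lambda=100,
        lambda_min_ratio=0.01,
        tol=1e-7,
        max_iter=100_000,
        seed=0,
    ):
        self.alpha_grid = alpha_grid
        self.n_repeats = n_repeats
        self.n_folds = n_folds
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y):
        cv_kwargs = dict(
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        grid = list(self.alpha_grid)
        if len(grid) == 1:
            best_alpha, self.alpha_mse_ = float(grid[0]), None
        else:
            best_alpha, self.alpha_mse_ = select_alpha(
                X,
                y,
                alpha_grid=grid,
                n_repeats=self.n_repeats,
                n_folds=self.n_folds,
                seed=self.seed,
                **cv_kwargs,
            )
        curve = cv_lambda(
            X, y, best_alpha, n_folds=self.n_folds, seed=derive_seed(self.seed, "final"), **cv_kwargs
        )
        model = enet_fit(
            X, y, best_alpha, curve.lambda_min, tol=self.tol, max_iter=self.max_iter
        )
        self.alpha_ = best_alpha
        self.lam_ = curve.lambda_min
        self.cv_curve_ = curve
        self.model_ = model
        self.coef_ = model.coef_array()
        self.intercept_ = model.intercept
        self.feature_ids_ = list(model.feature_ids)
        return self

    def predict(self, X):
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_
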