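"""Lasso stability selection and exact best-subset regression.

Stability selection repeats lasso fitting under re-randomized
cross-validation folds and tabulates how often each protein enters the
model; proteins selected in (nearly) every run form the core predictor set.
The best k-predictor model is then found exactly — minimizing training MSE
over all size-k subsets of the candidate pool — by a branch-and-bound search
in the Leaps-and-Bounds spirit, with exhaustive enumeration as a guaranteed
fallback for small pools.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .elastic_net import _BaseEstimator, cv_lambda, enet_fit


@dataclass
class SelectionFrequencyTable:
    """How often each feature was selected across repeated lasso runs."""

    drug_id: str
    n_runs: int
    frequency: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for f, v in self.frequency.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"frequency out of range for {f}: {v}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequency, dtype=float).sort_values(ascending=False)


def lasso_stability(
    X,
    y,
    n_runs: int = 1000,
    n_folds: int = 10,
    base_seed: int = 0,
    drug_id: str = "drug",
    **cv_kwargs,
) -> SelectionFrequencyTable:
    """Selection frequencies over repeated lasso (alpha=1) CV runs.

    Each run re-randomizes the fold assignment (seed derived from
    ``(base_seed, run)``), picks lambda at the CV minimum and records the
    nonzero feature set of the refit.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    counts: dict[str, int] = {}
    for r in range(n_runs):
        seed = derive_seed(base_seed, "stability", r)
        curve = cv_lambda(X, y, alpha=1.0, n_folds=n_folds, seed=seed, **cv_kwargs)
        model = enet_fit(X, y, alpha=1.0, lam=curve.lambda_min, **{
            k: v for k, v in cv_kwargs.items() if k in ("tol", "max_iter")
        })
        for f in model.coefficients:
            counts[f] = counts.get(f, 0) + 1
    freq = {f: c / n_runs for f, c in counts.items()}
    return SelectionFrequencyTable(drug_id=drug_id, n_runs=n_runs, frequency=freq)


def core_predictors(table: SelectionFrequencyTable, threshold: float) -> list[str]:
    """Features selected with frequency >= threshold, by descending frequency
    then id."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    hits = [(f, v) for f, v in table.frequency.items() if v >= threshold]
    hits.sort(key=lambda item: (-item[1], item[0]))
    return [f for f, _ in hits]


class LassoStabilitySelector(_BaseEstimator):
    """Stability-selection feature selector (scikit-learn style).

    fit(X, y) populates ``frequencies_`` (pd.Series, descending) and
    ``table_``; ``get_support(threshold)`` returns the core predictor ids.
    """

    def __init__(self, n_runs=1000, n_folds=10, seed=0, n_lambda=100, lambda_min_ratio=0.01):
        self.n_runs = n_runs
        self.n_folds = n_folds
        self.seed = seed
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio

    def fit(self, X, y):
        self.table_ = lasso_stability(
            X,
            y,
            n_runs=self.n_runs,
            n_folds=self.n_folds,
            base_seed=self.seed,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
        )
        self.frequencies_ = self.table_.as_series()
        return self

    def get_support(self, threshold: float = 1.0) -> list[str]:
        return core_predictors(self.table_, threshold)


@dataclass
class SubsetModel:
    """OLS refit of the exact best size-k predictor subset."""

    predictor_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    mse: float
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.predictor_ids) != len(self.coefficients):
            raise ValueError("predictor/coefficient length mismatch")
        if self.mse < 0 or self.r_squared > 1 + 1e-12:
            raise ValueError("invalid fit statistics")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + X[self.predictor_ids].to_numpy(dtype=float) @ self.coefficients


def _subset_rss(G: np.ndarray, c: np.ndarray, yty: float, idx: tuple[int, ...]) -> float:
    """RSS of centered OLS on the index subset via precomputed cross-products."""
    if not idx:
        return yty
    ii = np.asarray(idx)
    Gs = G[np.ix_(ii, ii)]
    cs = c[ii]
    try:
        beta = np.linalg.solve(Gs, cs)
    except np.linalg.LinAlgError:
        beta = np.linalg.pinv(Gs) @ cs
    return float(max(yty - cs @ beta, 0.0))


def _exhaustive_search(G, c, yty, k, order, ids):
    best = (np.inf, None)
    for combo in itertools.combinations(order, k):
        rss = _subset_rss(G, c, yty, combo)
        key = tuple(sorted(ids[j] for j in combo))
        if rss < best[0] - 1e-12 or (abs(rss - best[0]) <= 1e-12 and key < best[1][1]):
            best = (rss, (combo, key))
    return best[1][0], best[0]


def _branch_and_bound(G, c, yty, k, order, ids):
    """Exact DFS over size-k subsets with superset-RSS pruning.

    The RSS of the OLS fit on (chosen ∪ all remaining candidates) lower-bounds
    the RSS of every size-k completion, so branches whose bound cannot beat
    the incumbent are cut.
    """
    best_rss = np.inf
    best_key: tuple[str, ...] | None = None
    best_combo: tuple[int, ...] | None = None

    def recurse(start: int, chosen: tuple[int, ...]):
        nonlocal best_rss, best_key, best_combo
        if len(chosen) == k:
            rss = _subset_rss(G, c, yty, chosen)
            key = tuple(sorted(ids[j] for j in chosen))
            if rss < best_rss - 1e-12 or (
                abs(rss - best_rss) <= 1e-12 and (best_key is None or key < best_key)
            ):
                best_rss, best_key, best_combo = rss, key, chosen
            return
        remaining = order[start:]
        if len(chosen) + len(remaining) < k:
            return
        bound = _subset_rss(G, c, yty, chosen + tuple(remaining))
        if np.isfinite(best_rss) and bound > best_rss + 1e-12:
            return
        for i in range(start, len(order)):
            recurse(i + 1, chosen + (order[i],))

    recurse(0, ())
    return best_combo, best_rss


EXHAUSTIVE_LIMIT = 100_000


def best_subset(
    X: pd.DataFrame,
    y,
    k: int,
    candidate_ids=None,
    method: str = "auto",
) -> SubsetModel:
    """Exact lowest-MSE model with k predictors from a candidate pool.

    ``method``: "auto" enumerates exhaustively when C(|pool|, k) is small and
    otherwise branches-and-bounds; both return the identical optimum (ties
    broken toward the lexicographically smallest id tuple).  The winning
    subset is refit by OLS; MSE = RSS/n and R^2 = 1 - RSS/TSS are reported on
    the training data.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    ids_all = [str(col) for col in X.columns]
    pool = ids_all if candidate_ids is None else [str(f) for f in candidate_ids]
    missing = [f for f in pool if f not in set(ids_all)]
    if missing:
        raise ValueError(f"candidates absent from X: {missing}")
    if not (1 <= k <= len(pool)):
        raise ValueError("k must be in [1, |candidates|]")

    yv = np.asarray(y, dtype=float).ravel()
    sub = X[pool].to_numpy(dtype=float)
    n = sub.shape[0]
    Xc = sub - sub.mean(axis=0)
    yc = yv - yv.mean()
    G = Xc.T @ Xc
    c = Xc.T @ yc
    yty = float(yc @ yc)
    ids = list(pool)

    # visit strong marginal predictors first for tighter early bounds
    with np.errstate(divide="ignore", invalid="ignore"):
        diag = np.diag(G)
        score = np.where(diag > 0, c**2 / np.where(diag > 0, diag, 1.0), -np.inf)
    order = tuple(int(i) for i in np.argsort(-score, kind="stable"))

    n_combos = float(np.prod([(len(pool) - i) / (i + 1) for i in range(k)]))
    if method == "auto":
        method = "exhaustive" if n_combos <= EXHAUSTIVE_LIMIT else "branch_and_bound"
    if method == "exhaustive":
        combo, rss = _exhaustive_search(G, c, yty, k, order, ids)
    elif method == "branch_and_bound":
        combo, rss = _branch_and_bound(G, c, yty, k, order, ids)
    else:
        raise ValueError(f"unknown method {method!r}")

    chosen_ids = sorted(ids[j] for j in combo)
    design = np.column_stack([np.ones(n), X[chosen_ids].to_numpy(dtype=float)])
    coefs, *_ = np.linalg.lstsq(design, yv, rcond=None)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient subset; pseudo-inverse OLS fit", stacklevel=2)
    resid = yv - design @ coefs
    rss_refit = float(resid @ resid)
    tss = yty
    r2 = 1.0 - rss_refit / tss if tss > 0 else 0.0
    return SubsetModel(
        predictor_ids=chosen_ids,
        coefficients=coefs[1:],
        intercept=float(coefs[0]),
        mse=rss_refit / n,
        r_squared=float(r2),
    )


class BestSubsetRegressor(_BaseEstimator):
    """Exact best-subset OLS estimator (scikit-learn style).

    fit(X, y) exposes ``predictor_ids_``, ``coef_``, ``intercept_``,
    ``mse_``, ``r_squared_``.
    """

    def __init__(self, k=3, candidate_ids=None, method="auto"):
        self.k = k
        self.candidate_ids = candidate_ids
        self.method = method

    def fit(self, X, y):
        model = best_subset(X, y, self.k, candidate_ids=self.candidate_ids, method=self.method)
        self.model_ = model
        self.predictor_ids_ = model.predictor_ids
        self.coef_ = model.coefficients
        self.intercept_ = model.intercept
        self.mse_ = model.mse
        self.r_squared_ = model.r_squared
        return self

    def predict(self, X):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("BestSubsetRegressor.predict requires a DataFrame")
        return self.model_.predict(X)


@dataclass
class SubsetSweepResult:
    """Per-drug best-subset models over several k plus R^2 summaries."""

    results: pd.DataFrame                      # drug, k, predictors, r_squared, mse
    no_model_drugs: list[str]
    histograms: dict[int, dict] = field(default_factory=dict)
    mean_r2: dict[int, float] = field(default_factory=dict)


def subset_sweep(
    X: pd.DataFrame,
    drugs: pd.DataFrame,
    k_values=(1, 3),
    candidate_pools: dict[str, SelectionFrequencyTable] | dict[str, list] | None = None,
    n_bins: int = 10,
) -> SubsetSweepResult:
    """Best 1-/3-predictor models per drug from each drug's lasso pool.

    ``candidate_pools`` maps drug id to either a SelectionFrequencyTable
    (features with frequency > 0 form the pool) or an explicit id list; a
    missing/empty pool records the drug as having no model.  Returns a long
    table plus R^2 histogram counts and means per k.
    """
    rows = []
    no_model = []
    for drug in drugs.columns:
        pool = None
        if candidate_pools is not None:
            entry = candidate_pools.get(drug)
            if isinstance(entry, SelectionFrequencyTable):
                pool = [f for f, v in entry.frequency.items() if v > 0]
            elif entry is not None:
                pool = list(entry)
            if not pool:
                no_model.append(drug)
                continue
        y = drugs[drug]
        for k in k_values:
            k_used = min(k, len(pool)) if pool is not None else k
            model = best_subset(X, y, k_used, candidate_ids=pool)
            rows.append(
                {
                    "drug": drug,
                    "k": k,
                    "k_used": k_used,
                    "predictors": ",".join(model.predictor_ids),
                    "r_squared": model.r_squared,
                    "mse": model.mse,
                }
            )
    results = pd.DataFrame(rows, columns=["drug", "k", "k_used", "predictors", "r_squared", "mse"])

    histograms: dict[int, dict] = {}
    mean_r2: dict[int, float] = {}
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for k in k_values:
        r2 = results.loc[results["k"] == k, "r_squared"].to_numpy(dtype=float)
        if r2.size:
            counts, _ = np.histogram(np.clip(r2, 0.0, 1.0), bins=edges)
            histograms[k] = {"bin_edges": edges.tolist(), "counts": counts.tolist()}
            mean_r2[k] = float(r2.mean())
    return SubsetSweepResult(results, no_model, histograms, mean_r2)
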