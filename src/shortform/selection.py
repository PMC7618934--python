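"""Fold-consistency item selection with L1-penalized logistic regression.

The short form is derived inside five-fold nested cross-validation: for
each outer fold the regularization strength lambda is tuned on the
four-fold training portion by inner cross-validated binomial
log-likelihood, the model is refit on that whole training portion, and
the items with nonzero coefficients are recorded.  Items retained in at
least 4 of the 5 outer folds form the primary short form ("mini" set);
items retained in all 5 form the further-reduced "ultra" set.

Objective convention: (1/n) * negative binomial log-likelihood
+ lambda * sum|beta|, intercept unpenalized — the glmnet scaling, mapped
onto scikit-learn's C parameter as C = 1 / (n * lambda).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, KFold

from .instrument import CohortDataset, drop_zero_variance

#: coefficients below this magnitude count as excluded (solver epsilon guard)
ZERO_TOL = 1e-10


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class FoldPlan:
    """Cross-validation layout: outer folds estimate, inner folds tune."""

    n_outer_folds: int = 5
    n_inner_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def outer_splitter(self, seed: Optional[int] = None):
        s = self.seed if seed is None else seed
        cls = StratifiedKFold if self.stratified else KFold
        return cls(n_splits=self.n_outer_folds, shuffle=True, random_state=s)

    def inner_splitter(self, seed: int):
        cls = StratifiedKFold if self.stratified else KFold
        return cls(n_splits=self.n_inner_folds, shuffle=True, random_state=seed)


@dataclass
class SelectionResult:
    per_fold_items: list[list[str]]
    consistency_count: dict[str, int]
    mini_set: list[str]
    ultra_set: list[str]
    per_fold_lambda: list[float]

    def as_dict(self) -> dict:
        return {
            "per_fold_items": self.per_fold_items,
            "consistency_count": self.consistency_count,
            "mini_set": self.mini_set,
            "ultra_set": self.ultra_set,
            "per_fold_lambda": self.per_fold_lambda,
        }


def _as_arrays(features, outcome) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        cols = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        cols = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=int)
    return X, y, cols


def lambda_max(features, outcome) -> float:
    """Smallest lambda that zeroes every coefficient:
    max_j |x_j . (y - ybar)| / n under the (1/n)-scaled objective."""
    X, y, _ = _as_arrays(features, outcome)
    resid = y - y.mean()
    return float(np.max(np.abs(X.T @ resid)) / len(y))


def lambda_grid(lmax: float, n_lambda: int = 100, min_ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to lambda_max * min_ratio."""
    if lmax <= 0:
        raise SelectionError("lambda_max must be positive (is the outcome constant?)")
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def fit_l1_logistic(features, outcome, lam: float) -> tuple[np.ndarray, float]:
    """Fit L1-penalized logistic regression at penalty ``lam``.

    Returns (coefficients, intercept).  The convex subproblem is delegated
    to scikit-learn's liblinear solver with a large intercept scaling so
    the intercept is effectively unpenalized.
    """
    X, y, _ = _as_arrays(features, outcome)
    classes = np.unique(y)
    if classes.size < 2:
        raise SelectionError("outcome has a single class; cannot fit")
    if lam < 0:
        raise SelectionError("lambda must be non-negative")
    variances = X.var(axis=0)
    if np.any(variances == 0):
        bad = np.nonzero(variances == 0)[0]
        raise SelectionError(f"zero-variance feature columns at indices {bad.tolist()}")
    kwargs = dict(
        # lam = 0 degrades gracefully to an (effectively) unpenalized fit
        C=1.0 / (len(y) * lam) if lam > 0 else 1e10,
        solver="liblinear",
        intercept_scaling=1e4,
        tol=1e-7,
        max_iter=5000,
        random_state=0,  # liblinear shuffles internally; pin for determinism
    )
    try:  # sklearn >= 1.8 spells the L1 penalty via l1_ratio
        model = LogisticRegression(l1_ratio=1.0, **kwargs)
        model.fit(X, y)
    except (TypeError, ValueError):
        model = LogisticRegression(penalty="l1", **kwargs)
        model.fit(X, y)
    if model.n_iter_[0] >= 5000:
        raise SelectionError(f"L1 solver failed to converge at lambda={lam:g}")
    return model.coef_[0].copy(), float(model.intercept_[0])


def retained_items(coef: np.ndarray, columns: Sequence[str]) -> list[str]:
    """Item ids with coefficients of magnitude above :data:`ZERO_TOL`."""
    return [c for c, b in zip(columns, coef) if abs(b) > ZERO_TOL]


def _held_out_loglik(coef, intercept, X, y) -> float:
    eta = X @ coef + intercept
    # log-likelihood per observation; log_expit is numerically safe
    ll = np.where(y == 1, special.log_expit(eta), special.log_expit(-eta))
    return float(np.mean(ll))


def tune_lambda(
    train_features,
    train_outcome,
    plan: FoldPlan,
    grid: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> float:
    """Choose lambda by inner cross-validated binomial log-likelihood.

    Scans a descending log-spaced grid and returns the lambda with maximal
    mean held-out log-likelihood; exact ties resolve to the smaller lambda.
    """
    X, y, _ = _as_arrays(train_features, train_outcome)
    if np.unique(y).size < 2:
        raise SelectionError("outcome has a single class; cannot tune")
    if grid is None:
        grid = lambda_grid(lambda_max(X, y))
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 1:
        return float(grid[0])
    splitter = plan.inner_splitter(plan.seed if seed is None else seed)
    folds = list(splitter.split(X, y))
    for tr, _ in folds:
        if np.unique(y[tr]).size < 2:
            raise SelectionError("degenerate inner fold: single-class training portion")
    # a column can be constant within one inner fold; it carries no signal
    # there and is masked for that fold's fits
    masks = [X[tr].var(axis=0) > 0 for tr, _ in folds]
    mean_ll = np.empty(grid.size)
    for g, lam in enumerate(grid):
        lls = []
        for (tr, va), keep in zip(folds, masks):
            coef, intercept = fit_l1_logistic(X[tr][:, keep], y[tr], lam)
            lls.append(_held_out_loglik(coef, intercept, X[va][:, keep], y[va]))
        mean_ll[g] = np.mean(lls)
    best = 0
    for g in range(1, grid.size):
        if mean_ll[g] >= mean_ll[best]:  # >= walks ties toward smaller lambda
            best = g
    return float(grid[best])


def stability_select_matrix(
    features: pd.DataFrame,
    outcome: Sequence[int],
    plan: FoldPlan = FoldPlan(),
    consistency_threshold: int = 4,
    n_lambda: int = 100,
) -> SelectionResult:
    """Fold-consistency selection on a prepared binary feature matrix."""
    X, y, cols = _as_arrays(features, outcome)
    if not 1 <= consistency_threshold <= plan.n_outer_folds:
        raise SelectionError("consistency_threshold must lie in [1, n_outer_folds]")
    splitter = plan.outer_splitter()
    inner_seeds = np.random.SeedSequence(plan.seed).generate_state(plan.n_outer_folds) % (2**31)
    per_fold_items: list[list[str]] = []
    per_fold_lambda: list[float] = []
    for k, (tr, _te) in enumerate(splitter.split(X, y)):
        if np.unique(y[tr]).size < 2:
            raise SelectionError(f"outer fold {k}: single-class training portion")
        Xtr = X[tr]
        keep = Xtr.var(axis=0) > 0  # a column can be constant within one fold
        grid = lambda_grid(lambda_max(Xtr[:, keep], y[tr]), n_lambda=n_lambda)
        lam = tune_lambda(Xtr[:, keep], y[tr], plan, grid=grid, seed=int(inner_seeds[k]))
        coef, _ = fit_l1_logistic(Xtr[:, keep], y[tr], lam)
        kept_cols = [c for c, m in zip(cols, keep) if m]
        per_fold_items.append(retained_items(coef, kept_cols))
        per_fold_lambda.append(lam)
    counts = {c: sum(c in items for items in per_fold_items) for c in cols}
    mini = [c for c in cols if counts[c] >= consistency_threshold]
    ultra = [c for c in cols if counts[c] == plan.n_outer_folds]
    return SelectionResult(
        per_fold_items=per_fold_items,
        consistency_count=counts,
        mini_set=mini,
        ultra_set=ultra,
        per_fold_lambda=per_fold_lambda,
    )


def stability_select(
    dataset: CohortDataset,
    plan: FoldPlan = FoldPlan(),
    consistency_threshold: int = 4,
    n_lambda: int = 100,
) -> SelectionResult:
    """Derive the mini (>= threshold of 5 folds) and ultra (all folds) item
    sets from a scored cohort: psychosis-threshold cases are excluded and
    zero-variance items dropped before selection."""
    X, y = dataset.analysis_set()
    X, _removed = drop_zero_variance(X)
    return stability_select_matrix(
        X, y, plan=plan, consistency_threshold=consistency_threshold, n_lambda=n_lambda
    )
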