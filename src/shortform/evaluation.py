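"""Detection-performance estimation by repeated nested cross-validation.

A candidate item subset is evaluated against the full-scale any-item
label.  Classification uses the threshold-0 rule — a participant is
called positive if *any* subset item is endorsed — which mirrors the full
instrument's own scoring and therefore structurally forbids false
positives (a subset endorsement is also a full-scale endorsement), making
specificity and PPV identically 1 whenever defined.  Discrimination
(Harrell's C) instead comes from the predicted probabilities of an
L1-penalized logistic model refit on each training portion restricted to
the subset items.

Each repeat r uses a fresh seeded split (seed + r); 5 repeats x 5 outer
folds yield the 25 fold-level metric sets that are pooled into means and
normal 95% CIs.
"""

from __future__ import annotations

import warnings
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .instrument import CohortDataset
from .metrics import MetricSet, PooledPerformance, confusion_metrics, pool_metrics
from .selection import (
    FoldPlan,
    fit_l1_logistic,
    lambda_grid,
    lambda_max,
    tune_lambda,
)


class EvaluationError(ValueError):
    pass


def subset_classify(binary_row, subset: Sequence[str]) -> int:
    """Threshold-0 rule for one participant: 1 iff any subset item is 1."""
    subset = list(subset)
    if not subset:
        raise EvaluationError("empty item subset")
    if isinstance(binary_row, pd.Series):
        return int(binary_row.loc[subset].max() > 0)
    return int(np.asarray(binary_row)[subset].max() > 0)


def subset_classify_matrix(binary: pd.DataFrame, subset: Sequence[str]) -> np.ndarray:
    """Vectorized threshold-0 rule over a participants x items matrix."""
    subset = list(subset)
    if not subset:
        raise EvaluationError("empty item subset")
    missing = [s for s in subset if s not in binary.columns]
    if missing:
        raise EvaluationError(f"subset items not in matrix: {missing}")
    return (binary.loc[:, subset].to_numpy().max(axis=1) > 0).astype(int)


def _fold_predictions(
    X: pd.DataFrame,
    y: np.ndarray,
    subset: list[str],
    plan: FoldPlan,
    n_repeats: int,
    n_lambda: int,
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (test_index, truth, threshold0_prediction, model_probability)
    for every fold of every repeat; repeat r splits with seed plan.seed+r."""
    Xs = X.loc[:, subset]
    pred_all = subset_classify_matrix(X, subset)
    for r in range(n_repeats):
        split_seed = plan.seed + r
        splitter = plan.outer_splitter(seed=split_seed)
        inner_seeds = np.random.SeedSequence(split_seed).generate_state(
            plan.n_outer_folds
        ) % (2**31)
        for k, (tr, te) in enumerate(splitter.split(Xs, y)):
            if np.unique(y[tr]).size < 2:
                raise EvaluationError(f"repeat {r} fold {k}: single-class training portion")
            Xtr = Xs.iloc[tr].to_numpy(dtype=float)
            keep = Xtr.var(axis=0) > 0
            if not keep.any():
                raise EvaluationError(f"repeat {r} fold {k}: all subset items constant in training")
            grid = lambda_grid(lambda_max(Xtr[:, keep], y[tr]), n_lambda=n_lambda)
            lam = tune_lambda(Xtr[:, keep], y[tr], plan, grid=grid, seed=int(inner_seeds[k]))
            coef, intercept = fit_l1_logistic(Xtr[:, keep], y[tr], lam)
            Xte = Xs.iloc[te].to_numpy(dtype=float)[:, keep]
            proba = special.expit(Xte @ coef + intercept)
            yield te, y[te], pred_all[te], proba


def _fold_metrics(truth, pred, proba) -> MetricSet:
    if np.unique(truth).size < 2:
        warnings.warn(
            "test fold contains a single outcome class; undefined metrics recorded as missing",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-ratio NaN warnings already summarized above
        return confusion_metrics(pred, truth, scores=proba)


def repeated_nested_cv_evaluate(
    dataset: CohortDataset,
    subset: Sequence[str],
    plan: FoldPlan = FoldPlan(),
    n_repeats: int = 5,
    n_lambda: int = 100,
) -> PooledPerformance:
    """Estimate the subset's detection performance against the full scale.

    Returns pooled metrics over ``n_repeats x plan.n_outer_folds`` fold
    sets (25 by default).
    """
    subset = list(subset)
    if not subset:
        raise EvaluationError("empty item subset")
    X, y = dataset.analysis_set()
    per_fold = [
        _fold_metrics(truth, pred, proba)
        for _te, truth, pred, proba in _fold_predictions(
            X, y.to_numpy(), subset, plan, n_repeats, n_lambda
        )
    ]
    return pool_metrics(per_fold)
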