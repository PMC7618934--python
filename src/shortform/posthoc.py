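"""Post-hoc analyses: misclassification, severity contrast, fairness audit.

False negatives of the threshold-0 rule are participants who meet the
full-scale risk criteria only through items the short form omits; the
endorsement table of omitted items shows whether any single dropped item
drives the misses.  The severity contrast compares total symptom severity
between predicted classes with a Welch t-test.  The fairness audit
recomputes the detection metrics within demographic strata of the test
folds without refitting per stratum, so differences reflect the
classifier's behaviour, not stratum-specific models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import CohortDataset
from .evaluation import (
    EvaluationError,
    _fold_metrics,
    _fold_predictions,
    subset_classify_matrix,
)
from .metrics import PooledPerformance, pool_metrics, METRIC_NAMES
from .selection import FoldPlan


@dataclass
class MisclassificationReport:
    false_negative_ids: list[str]
    omitted_item_endorsement: dict[str, tuple[int, float]]
    n_false_negatives: int

    def as_dict(self) -> dict:
        return {
            "false_negative_ids": self.false_negative_ids,
            "n_false_negatives": self.n_false_negatives,
            "omitted_item_endorsement": {
                k: {"count": c, "share": s}
                for k, (c, s) in self.omitted_item_endorsement.items()
            },
        }


def misclassification_analysis(
    dataset: CohortDataset, subset: Sequence[str]
) -> MisclassificationReport:
    """Find full-scale positives missed by the subset rule and tabulate
    which omitted items they endorsed."""
    subset = list(subset)
    if not subset:
        raise EvaluationError("empty item subset")
    X, y = dataset.analysis_set()
    pred = subset_classify_matrix(X, subset)
    fn_mask = (y.to_numpy() == 1) & (pred == 0)
    fn_ids = list(X.index[fn_mask])
    omitted = [c for c in X.columns if c not in subset]
    table: dict[str, tuple[int, float]] = {}
    if fn_ids:
        counts = X.loc[fn_ids, omitted].sum(axis=0)
        for item, cnt in counts.items():
            if cnt > 0:
                table[item] = (int(cnt), float(cnt) / len(fn_ids))
    return MisclassificationReport(
        false_negative_ids=fn_ids,
        omitted_item_endorsement=table,
        n_false_negatives=len(fn_ids),
    )


@dataclass
class SeverityComparison:
    mean_no_risk: float
    sd_no_risk: float
    mean_risk: float
    sd_risk: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_difference_ci: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "mean_no_risk": self.mean_no_risk,
            "sd_no_risk": self.sd_no_risk,
            "mean_risk": self.mean_risk,
            "sd_risk": self.sd_risk,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "mean_difference_ci": list(self.mean_difference_ci),
        }


def severity_comparison(dataset: CohortDataset, subset: Sequence[str]) -> SeverityComparison:
    """Welch two-sample t-test of total severity (sum of raw per-item
    severities) between participants the subset rule calls negative
    ("no risk") and positive ("risk"); difference is no-risk minus risk."""
    subset = list(subset)
    if not subset:
        raise EvaluationError("empty item subset")
    X, _y = dataset.analysis_set()
    totals = dataset.severity_frame().loc[X.index].sum(axis=1).astype(float)
    pred = subset_classify_matrix(X, subset)
    no_risk = totals[pred == 0].to_numpy()
    risk = totals[pred == 1].to_numpy()
    if no_risk.size < 2 or risk.size < 2:
        raise EvaluationError("both predicted classes need at least 2 participants")
    res = stats.ttest_ind(no_risk, risk, equal_var=False)
    ci = res.confidence_interval(0.95)
    return SeverityComparison(
        mean_no_risk=float(no_risk.mean()),
        sd_no_risk=float(no_risk.std(ddof=1)),
        mean_risk=float(risk.mean()),
        sd_risk=float(risk.std(ddof=1)),
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        mean_difference_ci=(float(ci.low), float(ci.high)),
    )


def subgroup_audit(
    dataset: CohortDataset,
    subset: Sequence[str],
    group_field: str = "ethnicity_white",
    plan: FoldPlan = FoldPlan(),
    n_repeats: int = 5,
    n_lambda: int = 100,
) -> dict:
    """Stratified detection metrics for a demographic attribute.

    Models are fit on the full training folds; metrics are recomputed on
    the stratum members of each test fold and pooled per stratum.  A
    stratum with a single outcome class overall is reported as not
    evaluable.  Returns ``{"strata": {value: PooledPerformance-or-None},
    "difference": {metric: between-stratum mean gap}}``.
    """
    subset = list(subset)
    if group_field not in ("sex", "ethnicity_white"):
        raise EvaluationError(f"unknown group field {group_field!r}")
    X, y = dataset.analysis_set()
    demo = dataset.demographics_frame().loc[X.index, group_field]
    groups = demo.to_numpy()
    y_arr = y.to_numpy()
    values = sorted(pd.unique(groups), key=str)
    evaluable = {
        v: np.unique(y_arr[groups == v]).size == 2 for v in values
    }
    fold_sets: dict = {v: [] for v in values}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-class stratum folds yield NaNs by design
        for te, truth, pred, proba in _fold_predictions(
            X, y_arr, subset, plan, n_repeats, n_lambda
        ):
            g = groups[te]
            for v in values:
                m = g == v
                if not evaluable[v] or m.sum() < 2:
                    continue
                fold_sets[v].append(_fold_metrics(truth[m], pred[m], proba[m]))
    strata: dict = {}
    for v in values:
        strata[v] = pool_metrics(fold_sets[v]) if len(fold_sets[v]) >= 2 else None
    difference = {}
    pooled = [strata[v] for v in values if strata[v] is not None]
    if len(pooled) == 2:
        for name in METRIC_NAMES:
            a, b = pooled[0].mean[name], pooled[1].mean[name]
            difference[name] = a - b if not (math.isnan(a) or math.isnan(b)) else math.nan
    return {"group_field": group_field, "strata": strata, "difference": difference}
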