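"""Agreement, discrimination and classification metrics, and their pooling.

Conventions: Cohen's kappa is chance-corrected agreement from the 2x2
marginals; Harrell's C counts concordant (positive, negative) pairs with
ties scored 0.5, which for a binary outcome equals the AUC; ratios with a
zero denominator are reported as NaN with a warning, never silently as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

METRIC_NAMES = (
    "kappa",
    "c_index",
    "sensitivity",
    "specificity",
    "balanced_accuracy",
    "ppv",
    "npv",
    "f1",
)


class MetricError(ValueError):
    pass


@dataclass
class MetricSet:
    """One test fold's metric battery plus the confusion counts."""

    kappa: float = math.nan
    c_index: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    balanced_accuracy: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    f1: float = math.nan
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class PooledPerformance:
    """Per-fold metric sets pooled into means with normal 95% CIs."""

    per_fold: list[MetricSet]
    mean: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "n_folds": len(self.per_fold),
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "per_fold": [m.as_dict() | {"tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn}
                         for m in self.per_fold],
        }


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise MetricError(f"{name} must be binary 0/1")
    return v.astype(int)


def cohens_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Chance-corrected agreement between two binary labelings.

    kappa = (p_o - p_e) / (1 - p_e); when both raters agree perfectly and
    chance agreement is also 1 (single observed class), kappa is 1 by
    convention.
    """
    a = _check_binary(labels_a, "labels_a")
    b = _check_binary(labels_b, "labels_b")
    if a.shape != b.shape:
        raise MetricError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise MetricError("need at least 2 observations")
    p_o = float(np.mean(a == b))
    p_e = float(np.mean(a) * np.mean(b) + (1 - np.mean(a)) * (1 - np.mean(b)))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def harrell_c(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Concordance index: share of (positive, negative) pairs where the
    positive case scores higher; ties count 0.5.  Equals AUC for a binary
    outcome.  Computed via midranks (Mann-Whitney) in O(n log n)."""
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise MetricError("scores and labels length mismatch")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricError("labels must contain both classes")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return math.nan
    return num / den


def confusion_metrics(
    predicted: Sequence[int],
    truth: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> MetricSet:
    """Full classification battery from predicted vs true binary labels.

    ``scores`` (e.g. model probabilities), when given, feed the C-index;
    otherwise ``c_index`` stays NaN.
    """
    pred = _check_binary(predicted, "predicted")
    y = _check_binary(truth, "truth")
    if pred.shape != y.shape:
        raise MetricError(f"length mismatch: {pred.shape} vs {y.shape}")
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    se = _ratio(tp, tp + fn, "sensitivity")
    sp = _ratio(tn, tn + fp, "specificity")
    ppv = _ratio(tp, tp + fp, "PPV")
    npv = _ratio(tn, tn + fn, "NPV")
    ba = (se + sp) / 2
    f1 = math.nan
    if not (math.isnan(ppv) or math.isnan(se)) and (ppv + se) > 0:
        f1 = 2 * ppv * se / (ppv + se)
    kappa = cohens_kappa(pred, y)
    c = math.nan
    if scores is not None and 0 < y.sum() < y.size:
        c = harrell_c(scores, y)
    return MetricSet(
        kappa=kappa, c_index=c, sensitivity=se, specificity=sp,
        balanced_accuracy=ba, ppv=ppv, npv=npv, f1=f1,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def pool_metrics(per_fold: Sequence[MetricSet]) -> PooledPerformance:
    """Pool fold-level metric sets: per-metric arithmetic mean and normal
    95% CI (mean +/- 1.96 * sd / sqrt(k)) over the k non-missing folds."""
    per_fold = list(per_fold)
    if len(per_fold) < 2:
        raise MetricError("need at least 2 metric sets to pool")
    mean, lo, hi = {}, {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_fold], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            mean[name] = lo[name] = hi[name] = math.nan
            continue
        m = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        half = 1.96 * sd / math.sqrt(vals.size)
        mean[name], lo[name], hi[name] = m, m - half, m + half
    return PooledPerformance(per_fold=per_fold, mean=mean, ci_low=lo, ci_high=hi)
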