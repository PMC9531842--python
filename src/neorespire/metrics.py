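"""Binary classification metrics and model-agreement statistics.

Implements the standard confusion-matrix metrics directly from their
definitions — top-1 accuracy (TP+TN)/N, precision TP/(TP+FP), recall =
sensitivity TP/(TP+FN), F1 = 2PR/(P+R), specificity TN/(TN+FP) — plus AUC by
the trapezoidal rule over the empirical ROC of continuous scores, and
Bland-Altman agreement summaries (mean/min/max paired difference and limits
of agreement mean ± 1.96 sd) for comparing two classifiers' accuracies.

Zero-denominator metrics come back as NaN with a warning flag instead of
raising, so batch sweeps over degenerate cells do not abort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from neorespire.errors import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN; the four cells partition the samples."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if not np.isin(np.concatenate([y_true, y_pred]), [0, 1]).all():
        raise ValidationError("labels must be binary")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def roc_auc(y_true, scores) -> float:
    """Area under the empirical ROC curve by the trapezoidal rule.

    Sweeps the decision threshold over the sorted unique scores; ties are
    handled by grouping equal scores into one ROC step (this makes the
    trapezoid equal the Mann-Whitney statistic with tie correction).
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("labels and scores must have equal length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied-score run
    last_of_run = np.append(s_sorted[1:] != s_sorted[:-1], True)
    tpr = np.concatenate([[0.0], tps[last_of_run] / n_pos])
    fpr = np.concatenate([[0.0], fps[last_of_run] / n_neg])
    return float(np.trapezoid(tpr, fpr))


def all_metrics(c: ConfusionCounts, y_true=None, scores=None) -> dict:
    """Full metric report from confusion counts (AUC needs scores).

    Undefined ratios are NaN; their names are listed under ``undefined``.
    """
    if c.total < 1:
        raise ValidationError("need at least one sample")
    precision = _safe_ratio(c.tp, c.tp + c.fp)
    recall = _safe_ratio(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    report = {
        "top1": (c.tp + c.tn) / c.total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "sensitivity": recall,
        "specificity": _safe_ratio(c.tn, c.tn + c.fp),
    }
    if scores is not None:
        if y_true is None:
            raise ValidationError("AUC needs y_true alongside scores")
        report["auc"] = roc_auc(y_true, scores)
    report["undefined"] = sorted(k for k, v in report.items()
                                 if isinstance(v, float) and math.isnan(v))
    return report


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of paired differences a - b."""

    mean_diff: float
    min_diff: float
    max_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(acc_a, acc_b) -> AgreementStats:
    """Agreement between two paired accuracy series (differences a - b).

    Limits of agreement are mean ± 1.96 sd (sample sd of the differences).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired series must have equal length")
    if len(a) < 2:
        raise ValidationError("need at least two paired measurements")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        mean_diff=mean,
        min_diff=float(d.min()),
        max_diff=float(d.max()),
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=len(d),
    )
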