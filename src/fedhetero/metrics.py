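"""Diagnostic metrics for imbalanced binary classification.

Implements the evaluation suite used for lymph-node-metastasis detection:
balanced accuracy, sensitivity, specificity, precision, F1/F2, the
diagnostic odds ratio (DOR), ROC AUC, and the area under the
precision-recall curve as step-wise average precision.  The positive class
is LNM-positive (label 1); the default decision threshold on predicted
probability is 0.5.

Degenerate confusion matrices follow the reporting conventions of clinical
result tables rather than a smoothing correction: a DOR with a zero
denominator but positive numerator is ``+inf``; a 0/0 DOR and any metric
with an empty denominator are NaN (rendered "-").  A Haldane-Anscombe 0.5
correction is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "threshold_metrics",
    "roc_auc",
    "auprc",
    "evaluate_predictions",
    "REPORT_COLUMNS",
]

# column order of the serialized metric table (clinical-table order,
# with F2 and AUC appended)
REPORT_COLUMNS = [
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
    "dor",
    "auprc",
    "f2",
    "auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Flat bundle of threshold and ranking metrics (NaN where undefined)."""

    balanced_accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    f2: float
    dor: float
    auc: float = math.nan
    auprc: float = math.nan
    counts: ConfusionCounts | None = field(default=None, compare=False)

    def to_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in REPORT_COLUMNS}

    def to_row(self) -> dict[str, str]:
        """Render for a table: 4 decimals, inf, and "-" for undefined cells."""
        out = {}
        for c in REPORT_COLUMNS:
            v = getattr(self, c)
            if math.isnan(v):
                out[c] = "-"
            elif math.isinf(v):
                out[c] = "inf"
            else:
                out[c] = f"{v:.4f}"
        return out


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{name} must be binary 0/1, got values {uniq!r}")
    return arr.astype(int).ravel()


def confusion(labels, predictions) -> ConfusionCounts:
    """Exact integer confusion counts (positive class = 1)."""
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if y.size != p.size:
        raise ValueError("labels and predictions differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def _fbeta(precision: float, sensitivity: float, beta: float) -> float:
    if math.isnan(precision) or math.isnan(sensitivity):
        return math.nan
    den = beta**2 * precision + sensitivity
    if den == 0:
        return math.nan
    return (1 + beta**2) * precision * sensitivity / den


def diagnostic_odds_ratio(c: ConfusionCounts, haldane: bool = False) -> float:
    """(tp*tn)/(fp*fn) with table conventions for empty cells.

    With ``haldane`` a 0.5 continuity correction is added to every cell
    instead, which keeps the ratio finite.
    """
    if haldane:
        return ((c.tp + 0.5) * (c.tn + 0.5)) / ((c.fp + 0.5) * (c.fn + 0.5))
    num = c.tp * c.tn
    den = c.fp * c.fn
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def threshold_metrics(c: ConfusionCounts, haldane_dor: bool = False) -> MetricReport:
    """All threshold-dependent metrics from a confusion matrix."""
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    prec = _ratio(c.tp, c.tp + c.fp)
    ba = (sens + spec) / 2.0
    return MetricReport(
        balanced_accuracy=ba,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=_fbeta(prec, sens, 1.0),
        f2=_fbeta(prec, sens, 2.0),
        dor=diagnostic_odds_ratio(c, haldane=haldane_dor),
        counts=c,
    )


def roc_auc(labels, scores) -> float:
    """ROC area (Mann-Whitney with ties counted 1/2); NaN if one class only."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.size != s.size:
        raise ValueError("labels and scores differ in length")
    if len(np.unique(y)) < 2:
        return math.nan
    return float(roc_auc_score(y, s))


def auprc(labels, scores) -> float:
    """Average precision (step-wise precision-recall area); NaN if no positives."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.size != s.size:
        raise ValueError("labels and scores differ in length")
    if y.sum() == 0:
        return math.nan
    return float(average_precision_score(y, s))


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> MetricReport:
    """Full metric report from probabilities: threshold metrics at
    ``threshold`` plus ranking metrics (AUC, AUPRC)."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64).ravel()
    preds = (s >= threshold).astype(int)
    report = threshold_metrics(confusion(y, preds))
    return replace(report, auc=roc_auc(y, s), auprc=auprc(y, s))
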