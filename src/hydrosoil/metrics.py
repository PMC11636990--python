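"""Confusion-matrix metric suite for binary (one-vs-rest) classification.

Implements the sixteen metrics reported for cultivation-system prediction:
accuracy, sensitivity (TPR), specificity (TNR), precision (PPV), NPV, F1,
FPR, FNR, FDR, FOR, Matthews correlation (MCC), positive likelihood ratio
(LR+) and the critical success index (CSI), plus ROC points. Ratios with a
zero denominator are reported as NaN and flagged, never raised.

:func:`implied_metrics_from_rates` inverts (sensitivity, specificity,
precision) to the unique prevalence consistent with them and reconstructs the
full suite — useful for checking that a published metric table is internally
consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "metric_suite",
    "implied_metrics_from_rates",
    "roc_points",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """The four confusion cells. Real-valued cells are allowed so that
    prevalence-normalized (fractional) tables can reuse the same machinery."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """All derived metrics as proportions (accuracy 0.973, not 97.3).

    ``undefined`` lists the metric names whose denominator was zero; those
    fields hold NaN.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    f1: float
    fpr: float
    fnr: float
    fdr: float
    for_: float
    mcc: float
    lr_plus: float
    csi: float
    undefined: tuple[str, ...] = ()

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        """Metric name → value; ``percent=True`` scales rate metrics by 100
        (MCC and LR+ are left on their natural scales, as printed reports do)."""
        out = {}
        for f in fields(self):
            if f.name == "undefined":
                continue
            v = getattr(self, f.name)
            if percent and f.name not in ("mcc", "lr_plus"):
                v = v * 100.0
            out[f.name.rstrip("_")] = v
        return out


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Standard one-vs-rest confusion cells; tp+tn+fp+fn equals n."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    truth = y_true.astype(str) == str(positive_class)
    if not truth.any() and str(positive_class) not in set(y_true.astype(str)):
        raise ValueError(f"positive class {positive_class!r} absent from y_true alphabet")
    pred = y_pred.astype(str) == str(positive_class)
    tp = int(np.sum(truth & pred))
    tn = int(np.sum(~truth & ~pred))
    fp = int(np.sum(~truth & pred))
    fn = int(np.sum(truth & ~pred))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def metric_suite(counts: ConfusionCounts) -> MetricReport:
    """Compute the full metric suite from confusion cells.

    Degenerate cells (zero denominators) yield NaN entries flagged in
    ``undefined`` rather than exceptions.
    """
    if counts.total <= 0:
        raise ValueError("counts total must be positive")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: list[str] = []
    acc = (tp + tn) / counts.total
    sens = _ratio(tp, tp + fn, "sensitivity", undefined)
    spec = _ratio(tn, tn + fp, "specificity", undefined)
    prec = _ratio(tp, tp + fp, "precision", undefined)
    npv = _ratio(tn, tn + fn, "npv", undefined)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", undefined)
    fpr = 1.0 - spec if not math.isnan(spec) else math.nan
    fnr = 1.0 - sens if not math.isnan(sens) else math.nan
    fdr = 1.0 - prec if not math.isnan(prec) else math.nan
    for_ = 1.0 - npv if not math.isnan(npv) else math.nan
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", undefined)
    lr_plus = _ratio(sens, fpr, "lr_plus", undefined) if not math.isnan(sens) else math.nan
    csi = _ratio(tp, tp + fp + fn, "csi", undefined)
    return MetricReport(
        accuracy=acc, sensitivity=sens, specificity=spec, precision=prec, npv=npv,
        f1=f1, fpr=fpr, fnr=fnr, fdr=fdr, for_=for_, mcc=mcc, lr_plus=lr_plus,
        csi=csi, undefined=tuple(undefined),
    )


def implied_metrics_from_rates(
    sensitivity: float, specificity: float, precision: float
) -> MetricReport:
    """Full metric suite implied by (sensitivity, specificity, precision) alone.

    Bayes' rule fixes the prevalence p through
    ``precision = s·p / (s·p + (1−spec)·(1−p))``; solving gives
    ``p = v(1−c) / (s(1−v) + v(1−c))`` with s=sensitivity, c=specificity,
    v=precision. The normalized confusion cells (tp=s·p, fn=(1−s)·p,
    tn=c·(1−p), fp=(1−c)·(1−p)) then determine every remaining metric.
    """
    s, c, v = float(sensitivity), float(specificity), float(precision)
    for name, val in (("sensitivity", s), ("specificity", c), ("precision", v)):
        if not 0.0 < val < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {val}")
    den = s * (1.0 - v) + v * (1.0 - c)
    if den <= 0:
        raise ValueError("inconsistent rates: no prevalence in (0, 1) satisfies them")
    p = v * (1.0 - c) / den
    if not 0.0 < p < 1.0:
        raise ValueError("inconsistent rates: implied prevalence outside (0, 1)")
    cells = ConfusionCounts(
        tp=s * p, fn=(1.0 - s) * p, tn=c * (1.0 - p), fp=(1.0 - c) * (1.0 - p)
    )
    return metric_suite(cells)


def roc_points(y_true, scores, positive_class) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs from a descending sweep over the unique scores.

    Starts at (0, 0) — threshold above every score — and ends at (1, 1).
    Raises if the truth vector contains a single class (rates undefined).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores lengths differ")
    truth = y_true.astype(str) == str(positive_class)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: y_true contains a single class")
    points = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tpr = np.sum(pred & truth) / n_pos
        fpr = np.sum(pred & ~truth) / n_neg
        points.append((float(fpr), float(tpr)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points
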