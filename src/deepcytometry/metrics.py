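"""Multiclass evaluation metrics: per-class and micro/macro/weighted
precision, recall and F1, accuracy, balanced accuracy, and one-vs-rest
ROC / precision-recall curves with micro and macro averaging.

All quantities derive from per-class one-vs-rest confusion counts.  For
class c, with condition positives CP_c = TP_c + FN_c:

* precision_c = TP_c / (TP_c + FP_c), recall_c = TP_c / (TP_c + FN_c),
  F1_c = 2 * precision_c * recall_c / (precision_c + recall_c)
* micro averaging pools the counts over classes before forming
  precision/recall (for single-label multiclass data micro-F1 equals plain
  accuracy);
* macro averaging gives each class equal weight 1/3;
* weighted averaging uses class-prevalence weights w_c = CP_c / N
  (so sum_c w_c = 1).

Balanced accuracy (BACC) is reported in its multiclass form, the mean of
per-class recalls; the binary form (mean of sensitivity and specificity)
is provided for the one-vs-rest iso-contour utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CurveResult",
    "UndefinedCurveError",
    "confusion_counts",
    "classwise_metrics",
    "averaged_f1",
    "accuracy_and_bacc",
    "binary_bacc",
    "full_report",
    "curve",
    "averaged_curve",
    "iso_bacc_contour",
    "iso_f1_contour",
]

N_CLASSES = 3


class UndefinedCurveError(ValueError):
    """ROC requested for a label set with no positives or no negatives."""


def _safe_div(num, den):
    """Elementwise num/den with the 0/0 -> 0 convention."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    return out


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest tallies over N examples."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n: int

    @property
    def condition_positive(self) -> np.ndarray:
        return self.tp + self.fn

    @property
    def condition_negative(self) -> np.ndarray:
        return self.tn + self.fp

    @property
    def weights(self) -> np.ndarray:
        """Class-prevalence weights w_c = CP_c / (CP_c + CN_c) = CP_c / N."""
        return _safe_div(self.condition_positive,
                         self.condition_positive + self.condition_negative)


def confusion_counts(y_true, y_pred, n_classes: int = N_CLASSES) -> ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class from hard label vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"unknown {name} label value")
    n = len(y_true)
    tp = np.zeros(n_classes, dtype=int)
    fp = np.zeros(n_classes, dtype=int)
    fn = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        tp[c] = np.sum((y_pred == c) & (y_true == c))
        fp[c] = np.sum((y_pred == c) & (y_true != c))
        fn[c] = np.sum((y_pred != c) & (y_true == c))
    tn = n - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn, n)


def classwise_metrics(counts: ConfusionCounts):
    """Per-class (precision, recall, F1, degenerate flags); a class with no
    predicted (or no true) members gets 0 and is flagged."""
    precision = _safe_div(counts.tp, counts.tp + counts.fp)
    recall = _safe_div(counts.tp, counts.tp + counts.fn)
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    degenerate = ((counts.tp + counts.fp) == 0) | ((counts.tp + counts.fn) == 0)
    return precision, recall, f1, degenerate


def averaged_f1(counts: ConfusionCounts, scheme: str):
    """Averaged (precision, recall, F1) under 'micro', 'macro' or 'weighted'
    averaging."""
    if scheme == "micro":
        precision = _safe_div(counts.tp.sum(), counts.tp.sum() + counts.fp.sum())
        recall = _safe_div(counts.tp.sum(), counts.tp.sum() + counts.fn.sum())
        f1 = _safe_div(2.0 * precision * recall, precision + recall)
        return float(precision), float(recall), float(f1)
    prec_c, rec_c, f1_c, _ = classwise_metrics(counts)
    if scheme == "macro":
        w = np.full(len(prec_c), 1.0 / len(prec_c))
    elif scheme == "weighted":
        w = counts.weights
    else:
        raise ValueError(f"unknown averaging scheme: {scheme!r}")
    return float(w @ prec_c), float(w @ rec_c), float(w @ f1_c)


def accuracy_and_bacc(y_true, y_pred) -> tuple[float, float]:
    """Accuracy (fraction of correct predictions) and multiclass balanced
    accuracy (macro-averaged recall)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    acc = float(np.mean(y_true == y_pred))
    counts = confusion_counts(y_true, y_pred)
    _, rec, _, _ = classwise_metrics(counts)
    return acc, float(rec.mean())


def binary_bacc(sensitivity: float, specificity: float) -> float:
    """Binary balanced accuracy: arithmetic mean of sensitivity and
    specificity (used for one-vs-rest iso-contours)."""
    return 0.5 * (sensitivity + specificity)


@dataclass
class MetricsReport:
    """Every score the evaluation formalism defines, from one prediction set."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    micro: tuple
    macro: tuple
    weighted: tuple
    accuracy: float
    balanced_accuracy: float
    counts: ConfusionCounts = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                "precision": list(map(float, self.precision)),
                "recall": list(map(float, self.recall)),
                "f1": list(map(float, self.f1)),
            },
            "micro": {"precision": self.micro[0], "recall": self.micro[1],
                      "f1": self.micro[2]},
            "macro": {"precision": self.macro[0], "recall": self.macro[1],
                      "f1": self.macro[2]},
            "weighted": {"precision": self.weighted[0],
                         "recall": self.weighted[1], "f1": self.weighted[2]},
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
        }


def full_report(y_true, y_pred) -> MetricsReport:
    counts = confusion_counts(y_true, y_pred)
    precision, recall, f1, _ = classwise_metrics(counts)
    acc, bacc = accuracy_and_bacc(y_true, y_pred)
    return MetricsReport(
        precision=precision, recall=recall, f1=f1,
        micro=averaged_f1(counts, "micro"),
        macro=averaged_f1(counts, "macro"),
        weighted=averaged_f1(counts, "weighted"),
        accuracy=acc, balanced_accuracy=bacc, counts=counts,
    )


# ---------------------------------------------------------------------------
# threshold-sweep curves

@dataclass
class CurveResult:
    kind: str       # 'roc' | 'pr'
    scope: str      # 'class0'.. | 'micro' | 'macro'
    x: np.ndarray   # ROC: FPR ascending; PR: recall
    y: np.ndarray   # ROC: TPR; PR: precision
    thresholds: np.ndarray
    area: float


def _sweep(scores, labels):
    """Cumulative TP/FP at each distinct descending threshold (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    tp = np.cumsum(l)
    fp = np.cumsum(1 - l)
    # keep the last index of every tie group
    keep = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    return s[keep], tp[keep], fp[keep]


def curve(scores, labels, kind: str = "roc") -> CurveResult:
    """One-vs-rest ROC or PR curve with thresholds swept over the unique
    scores (descending, ties grouped).

    ROC area is trapezoidal (equal to the probability that a random
    positive outranks a random negative, ties counting 1/2).  PR area uses
    step-wise (rectangular) interpolation in recall, which avoids the
    optimistic bias of linear interpolation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    P = int(labels.sum())
    Nn = len(labels) - P
    if kind == "roc":
        if P == 0 or Nn == 0:
            raise UndefinedCurveError(
                "ROC needs at least one positive and one negative")
        thr, tp, fp = _sweep(scores, labels)
        fpr = np.r_[0.0, fp / Nn]
        tpr = np.r_[0.0, tp / P]
        area = float(np.trapezoid(tpr, fpr))
        return CurveResult("roc", "class", fpr, tpr, thr, area)
    elif kind == "pr":
        if P == 0:
            raise UndefinedCurveError("PR needs at least one positive")
        thr, tp, fp = _sweep(scores, labels)
        recall = tp / P
        precision = tp / (tp + fp)
        area = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
        return CurveResult("pr", "class", recall, precision, thr, area)
    raise ValueError("kind must be 'roc' or 'pr'")


def _step_lookup(x, y, grid):
    """Right-continuous step interpolation of (x, y) onto grid."""
    idx = np.searchsorted(x, grid, side="left")
    idx = np.clip(idx, 0, len(y) - 1)
    return y[idx]


def averaged_curve(score_matrix, y_true, scope: str = "micro",
                   kind: str = "roc") -> CurveResult:
    """Micro- or macro-averaged one-vs-rest curve over the three classes.

    Micro pools every (example, class) score/indicator pair into one binary
    problem.  Macro evaluates each class's curve on a common x grid (linear
    interpolation for ROC, step interpolation for PR) and averages; a class
    whose curve is undefined is skipped with a warning.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    n_classes = score_matrix.shape[1]
    onehot = np.zeros_like(score_matrix, dtype=int)
    onehot[np.arange(len(y_true)), y_true] = 1
    if scope == "micro":
        pooled = curve(score_matrix.ravel(), onehot.ravel(), kind)
        return CurveResult(kind, "micro", pooled.x, pooled.y,
                           pooled.thresholds, pooled.area)
    if scope != "macro":
        raise ValueError("scope must be 'micro' or 'macro'")
    curves = []
    for c in range(n_classes):
        try:
            curves.append(curve(score_matrix[:, c], onehot[:, c], kind))
        except UndefinedCurveError:
            import warnings
            warnings.warn(f"class {c} skipped from macro average "
                          "(degenerate labels)", RuntimeWarning)
    if not curves:
        raise UndefinedCurveError("no class curve is defined")
    grid = np.unique(np.concatenate([c.x for c in curves]))
    if kind == "roc":
        ys = [np.interp(grid, c.x, c.y) for c in curves]
    else:
        ys = [_step_lookup(c.x, c.y, grid) for c in curves]
    y = np.mean(ys, axis=0)
    # macro area is the mean of the class areas (the standard definition);
    # the interpolated mean curve is for plotting and its own integral can
    # differ slightly where a class curve has vertical segments
    area = float(np.mean([c.area for c in curves]))
    return CurveResult(kind, "macro", grid, y, np.array([]), area)


# ---------------------------------------------------------------------------
# iso-contours (plot guides)

def iso_bacc_contour(level: float, n_points: int = 101):
    """(FPR, TPR) points of constant binary balanced accuracy:
    TPR = 2*level - (1 - FPR), clipped to the unit square."""
    fpr = np.linspace(0.0, 1.0, n_points)
    tpr = 2.0 * level - (1.0 - fpr)
    mask = (tpr >= 0.0) & (tpr <= 1.0)
    return fpr[mask], tpr[mask]


def iso_f1_contour(level: float, n_points: int = 101):
    """(recall, precision) points of constant F1:
    precision = level * recall / (2*recall - level)."""
    recall = np.linspace(level / 2.0 + 1e-9, 1.0, n_points)
    precision = level * recall / (2.0 * recall - level)
    mask = (precision >= 0.0) & (precision <= 1.0)
    return recall[mask], precision[mask]
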