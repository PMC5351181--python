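"""Confusion-matrix and ranking measures for imbalanced binary classification.

Degenerate ratios (zero denominator) return 0 and set a flag rather than
raising, so that a pathological classifier scores worst instead of aborting
an experiment sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "BasicMeasures",
    "confusion",
    "basic_measures",
    "f_value",
    "g_mean",
    "auc",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class BasicMeasures:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    undefined: set = field(default_factory=set)


def confusion(true_labels, predicted_labels, positive_label) -> ConfusionMatrix:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    alphabet = set(np.unique(t).tolist()) | set(np.unique(p).tolist())
    if positive_label not in alphabet:
        raise ValueError("positive_label absent from the label alphabet")
    pos_t = t == positive_label
    pos_p = p == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
    )


def _ratio(num, den, name, undefined):
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def basic_measures(cm: ConfusionMatrix) -> BasicMeasures:
    """Accuracy, sensitivity (recall), specificity and precision."""
    undefined = set()
    return BasicMeasures(
        accuracy=(cm.tp + cm.tn) / cm.n,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, "sensitivity", undefined),
        specificity=_ratio(cm.tn, cm.fp + cm.tn, "specificity", undefined),
        precision=_ratio(cm.tp, cm.tp + cm.fp, "precision", undefined),
        undefined=undefined,
    )


def f_value(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall; 0 when either is 0."""
    b = basic_measures(cm)
    if b.precision == 0.0 or b.sensitivity == 0.0:
        return 0.0
    return 2.0 / (1.0 / b.precision + 1.0 / b.sensitivity)


def g_mean(cm: ConfusionMatrix) -> float:
    """Geometric mean of sensitivity and specificity."""
    b = basic_measures(cm)
    return float(np.sqrt(b.sensitivity * b.specificity))


def auc(true_labels, scores, positive_label) -> float:
    """Area under the ROC curve by the trapezoidal rule with tied scores
    grouped; equals the normalised Mann-Whitney U statistic (ties counted
    one half).  Constant scores give 0.5.
    """
    t = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if len(t) != len(s):
        raise ValueError("label and score vectors differ in length")
    pos = t == positive_label
    n_pos = int(pos.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    pos_sorted = pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # keep only the last index of each tied-score group
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return float(np.trapezoid(tpr, fpr))
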