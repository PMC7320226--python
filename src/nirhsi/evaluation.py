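"""Scoring classification maps against ground truth.

Cancer is the positive class.  Accuracy = (TP + TN) / (TP + FP + TN + FN);
sensitivity = TP / (TP + FN); specificity = TN / (TN + FP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sam import UNCLASSIFIED, ClassificationMap

log = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "Metrics", "confusion", "metrics"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float


def confusion(
    pred: ClassificationMap,
    truth: np.ndarray,
    evaluate_on: np.ndarray,
    positive: str = "cancer",
    negative: str = "normal",
    truth_codes: dict[str, int] | None = None,
) -> ConfusionCounts:
    """Pixel confusion counts over ``evaluate_on == 1``.

    ``truth`` is a labeled mask holding the codes in ``truth_codes``
    (default ``{"normal": 1, "cancer": 2}``).  Unclassified predictions count
    as errors against their truth class; their number is logged.
    """
    truth_codes = truth_codes or {"normal": 1, "cancer": 2}
    truth = np.asarray(truth)
    sel = np.asarray(evaluate_on).astype(bool)
    if truth.shape != pred.labels.shape or sel.shape != truth.shape:
        raise ValueError("prediction, truth, and evaluation masks must share a shape")
    if not sel.any():
        raise ValueError("no pixels selected for evaluation")

    known = np.isin(truth, [truth_codes[positive], truth_codes[negative]])
    sel = sel & known

    t_pos = truth[sel] == truth_codes[positive]
    p = pred.labels[sel]
    n_uncl = int(np.sum(p == UNCLASSIFIED))
    if n_uncl:
        log.info("%d unclassified pixels counted as errors", n_uncl)
    p_pos = p == (pred.class_names.index(positive) + 1)
    p_neg = p == (pred.class_names.index(negative) + 1)

    return ConfusionCounts(
        tp=int(np.sum(t_pos & p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        tn=int(np.sum(~t_pos & p_neg)),
        fn=int(np.sum(t_pos & ~p_pos)),
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity from confusion counts.

    Undefined ratios (no positives, or no negatives, among the evaluated
    pixels) are reported as NaN with a warning.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics over zero pixels")
    acc = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fn > 0:
        sens = counts.tp / (counts.tp + counts.fn)
    else:
        log.warning("sensitivity undefined (no positive pixels)")
        sens = float("nan")
    if counts.tn + counts.fp > 0:
        spec = counts.tn / (counts.tn + counts.fp)
    else:
        log.warning("specificity undefined (no negative pixels)")
        spec = float("nan")
    return Metrics(acc, sens, spec)
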