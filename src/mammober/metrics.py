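"""Confusion-matrix bookkeeping and the six classification metrics.

The positive class is *malignant* (clinical convention: a positive screen
flags suspected cancer). Metrics are accuracy, sensitivity (recall on
malignant), specificity (recall on benign), precision (PPV), negative
predictive value, and the F-score written directly in counts,
F = TP / (TP + 0.5 (FP + FN)), which equals the harmonic mean of precision
and sensitivity whenever both are defined.

A metric whose denominator is zero is returned as NaN — an explicit
"undefined" marker — rather than silently coerced to 0 or 1, so degenerate
folds cannot hide in aggregate tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionMatrix", "confusion", "metrics", "METRIC_ORDER"]

# Column order used in CSV/reporting output.
METRIC_ORDER = ("accuracy", "sensitivity", "specificity", "precision",
                "npv", "f_score")

_VALID = frozenset({"benign", "malignant"})


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive: str = "malignant",
) -> ConfusionMatrix:
    """Count TP/FP/TN/FN over paired label sequences."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    unknown = (set(true_labels) | set(predicted_labels)) - _VALID
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    t = np.asarray([lab == positive for lab in true_labels])
    p = np.asarray([lab == positive for lab in predicted_labels])
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The six metrics; NaN marks an undefined (0/0) ratio."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "precision": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "f_score": _ratio(cm.tp, cm.tp + 0.5 * (cm.fp + cm.fn)),
    }
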