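"""Confusion counts and the performance metrics used in the comparison.

Accuracy = (TP + TN) / (TP + TN + FP + FN)
F1       = 2 TP / (2 TP + FP + FN), with F1 = 0 when 2 TP + FP + FN = 0
(no positives anywhere in truth or prediction), by declared convention.
The positive label defaults to 1 (the disease-positive analogue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidArgumentError(f"{name} must be a non-negative integer")

    @property
    def n_test(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(y_true, y_pred, positive_label: int = 1) -> ConfusionCounts:
    """Tally TP/FN/TN/FP with the declared positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.ndim != 1 or y_true.shape != y_pred.shape:
        raise InvalidArgumentError("y_true and y_pred must be equal-length vectors")
    if y_true.size < 1:
        raise InvalidArgumentError("empty vectors")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise InvalidArgumentError("entries must be 0/1")
    pos_true = y_true == positive_label
    pos_pred = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_true & pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """Proportion of test samples classified correctly."""
    if counts.n_test < 1:
        raise InvalidArgumentError("confusion counts sum to zero")
    return (counts.tp + counts.tn) / counts.n_test


def f1(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall for the positive class."""
    if counts.n_test < 1:
        raise InvalidArgumentError("confusion counts sum to zero")
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 0.0
    return 2 * counts.tp / denom


METRICS = {"accuracy": accuracy, "f1": f1}


def score(y_true, y_pred, metric: str, positive_label: int = 1) -> float:
    """Compute a named metric ("accuracy" or "f1") from raw vectors."""
    try:
        fn_ = METRICS[metric]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown metric {metric!r}; available: {sorted(METRICS)}"
        ) from None
    return fn_(confusion(y_true, y_pred, positive_label))
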