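"""Binary-classifier scoring against ground-truth labels.

The Matthews correlation coefficient (MCC) is the Pearson correlation of the
binary prediction and truth vectors; it ranges over [-1, 1] and is robust to
class imbalance.  Any zero marginal leaves the MCC undefined, which is
reported as NaN (never coerced to 0).  Accuracy is the standard
``(tp + tn) / total``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "mcc",
    "sensitivity",
    "specificity",
    "accuracy",
    "score_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one pair")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_bool_array(flags: Sequence) -> np.ndarray:
    arr = np.asarray(
        [bool(f) if not isinstance(f, str) else f == "present" for f in flags]
    )
    return arr


def confusion(predicted: Sequence, truth: Sequence) -> ConfusionMatrix:
    """Confusion matrix of paired binary flags (bool-likes or 'present'/'absent')."""
    p = _as_bool_array(predicted)
    t = _as_bool_array(truth)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(t)} truths")
    if len(p) == 0:
        raise ValueError("cannot score empty inputs")
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; NaN when any marginal is zero."""
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return math.nan
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def sensitivity(cm: ConfusionMatrix) -> float:
    """True-positive rate tp/(tp+fn); NaN if no positive truths exist."""
    if cm.tp + cm.fn == 0:
        return math.nan
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """True-negative rate tn/(tn+fp); NaN if no negative truths exist."""
    if cm.tn + cm.fp == 0:
        return math.nan
    return cm.tn / (cm.tn + cm.fp)


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def score_table(results: dict[str, tuple[Sequence, Sequence]]) -> pd.DataFrame:
    """Per-method metrics table from ``{method: (predicted, truth)}`` pairs."""
    rows = []
    for method, (pred, truth) in results.items():
        cm = confusion(pred, truth)
        rows.append(
            {
                "method": method,
                "tp": cm.tp,
                "fp": cm.fp,
                "fn": cm.fn,
                "tn": cm.tn,
                "mcc": mcc(cm),
                "sensitivity": sensitivity(cm),
                "specificity": specificity(cm),
                "accuracy": accuracy(cm),
            }
        )
    return pd.DataFrame(rows)
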