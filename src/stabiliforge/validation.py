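"""Confusion-matrix evaluation of stability predictions.

Given predicted and experimental ddG maps over the same mutations, a
mutation is *experimentally stabilizing* when its measured ddG is strictly
negative, and *predicted stabilizing* when the prediction is at or below a
decision threshold (0 kcal/mol by default; moving it to the cascade
thresholds reproduces stricter operating points).  Sensitivity,
specificity and false discovery rate are reported to 3 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .formats_io import Mutation


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    false_discovery_rate: float


def confusion_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity, specificity and FDR, rounded to 3 decimals.

    FDR is defined as 0.0 when nothing is predicted positive (tp+fp = 0),
    so operating points that predict nothing stay well-defined.
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: no experimental positives")
    if counts.tn + counts.fp == 0:
        raise ValueError("specificity undefined: no experimental negatives")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    fdr = (counts.fp / (counts.tp + counts.fp)
           if counts.tp + counts.fp > 0 else 0.0)
    return ConfusionMetrics(
        sensitivity=round(sens, 3),
        specificity=round(spec, 3),
        false_discovery_rate=round(fdr, 3),
    )


def classify_predictions(
    predicted_ddg: Mapping[Mutation, float],
    experimental_ddg: Mapping[Mutation, float],
    decision_threshold: float = 0.0,
) -> ConfusionCounts:
    """Tally a confusion matrix of stabilizing-mutation calls.

    Positive class: experimentally stabilizing (ddG < 0, strictly).
    Predicted positive: predicted ddG <= ``decision_threshold``.
    """
    missing = set(predicted_ddg) ^ set(experimental_ddg)
    if missing:
        names = ", ".join(sorted(str(m) for m in missing))
        raise KeyError(f"prediction/experiment key mismatch: {names}")
    tp = fp = tn = fn = 0
    for m, pred in predicted_ddg.items():
        exp_pos = experimental_ddg[m] < 0.0
        pred_pos = pred <= decision_threshold
        if pred_pos and exp_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif exp_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
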