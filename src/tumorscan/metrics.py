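"""Pixel-level segmentation evaluation.

Predicted and ground-truth masks are compared pixel by pixel into
TP/FP/FN/TN tallies, from which the standard scores follow:

    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    Dice        = 2 TP / (2 TP + FP + FN)
    accuracy    = (TP + TN) / (TP + FP + FN + TN)

A score whose denominator is zero is reported as undefined (None), never
silently coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricSet:
    precision: float | None
    recall: float | None
    specificity: float | None
    dice: float | None
    accuracy: float | None

    def rounded(self, ndigits: int = 4) -> dict:
        """Scores rounded for reporting; full precision is kept internally."""
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Pixel-wise TP/FP/FN/TN between a predicted and a reference mask."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Scores from a confusion tally; undefined ratios come back as None."""
    return MetricSet(
        precision=_ratio(c.TP, c.TP + c.FP),
        recall=_ratio(c.TP, c.TP + c.FN),
        specificity=_ratio(c.TN, c.TN + c.FP),
        dice=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
        accuracy=_ratio(c.TP + c.TN, c.total),
    )
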