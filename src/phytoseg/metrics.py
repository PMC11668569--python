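"""Confusion-matrix accuracy suite: CSI, POD, FAR, OA, Kappa.

Disease is the positive class (label 1). Note the FAR here is the
false-positive rate FP / (FP + TN) over actual negatives — not the
forecasting-literature false-alarm *ratio* FP / (TP + FP). Degenerate
denominators yield 0 with a warning so batch tables stay numeric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import BinaryMask

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "csi",
    "pod",
    "far",
    "oa",
    "kappa",
    "all_metrics",
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

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionMatrix:
    """Pixel counts of a predicted mask against ground truth."""
    p = np.asarray(pred.array if isinstance(pred, BinaryMask) else pred, dtype=bool)
    t = np.asarray(truth.array if isinstance(truth, BinaryMask) else truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0")
        return 0.0
    return num / den


def csi(cm: ConfusionMatrix) -> float:
    """Critical Success Index TP / (TP + FN + FP): positive-class overlap."""
    return _ratio(cm.tp, cm.tp + cm.fn + cm.fp, "CSI")


def pod(cm: ConfusionMatrix) -> float:
    """Probability of Detection TP / (TP + FN), the true-positive rate."""
    return _ratio(cm.tp, cm.tp + cm.fn, "POD")


def far(cm: ConfusionMatrix) -> float:
    """False Alarm Rate FP / (FP + TN), the false-positive rate."""
    return _ratio(cm.fp, cm.fp + cm.tn, "FAR")


def oa(cm: ConfusionMatrix) -> float:
    """Overall Accuracy (TP + TN) / total."""
    return _ratio(cm.tp + cm.tn, cm.total, "OA")


def kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (P0 - Pc) / (1 - Pc) with P0 = OA and
    Pc the product-marginal chance agreement."""
    n = cm.total
    if n == 0:
        warnings.warn("Kappa: empty matrix, returning 0")
        return 0.0
    p0 = (cm.tp + cm.tn) / n
    pc = (
        (cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fn + cm.tn) * (cm.fp + cm.tn)
    ) / (n * n)
    if pc == 1.0:
        warnings.warn("Kappa: degenerate marginals (Pc = 1), returning 0")
        return 0.0
    return (p0 - pc) / (1.0 - pc)


def all_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    return {
        "CSI": csi(cm),
        "POD": pod(cm),
        "FAR": far(cm),
        "OA": oa(cm),
        "Kappa": kappa(cm),
    }
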