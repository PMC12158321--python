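"""Segmentation scoring and no-reference sharpness measures.

Segmentation quality is reported as precision, accuracy, intersection over
union (IOU) and recall from per-pixel confusion counts; sequences are
micro-averaged (counts pooled over frames before dividing).

Sharpness uses three classical focus measures built from local intensity
differences — Brenner (squared offset-2 difference), Roberts (squared
cross differences of the 2x2 neighbourhood) and SMD2 (product of the two
forward differences) — plus the relative-difference comparison used to
contrast acquisitions: ``(reference - smaller) / reference`` with the
sharper measurement as reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "ConfusionCounts",
    "SegmentationScores",
    "SharpnessReport",
    "confusion_counts",
    "segmentation_metrics",
    "pooled_metrics",
    "sharpness_brenner",
    "sharpness_roberts",
    "sharpness_smd2",
    "sharpness_report",
    "relative_difference",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class SegmentationScores:
    precision: float
    accuracy: float
    iou: float
    recall: float
    #: True when any score had an empty denominator (reported as 0).
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "precision": self.precision, "accuracy": self.accuracy,
            "iou": self.iou, "recall": self.recall, "degenerate": self.degenerate,
        }


def _as_bool(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool and not np.isin(np.unique(m), (0, 1, 255)).all():
        raise InvalidArgumentError(f"{name} must be binary")
    return m.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    p = _as_bool(pred, "pred")
    t = _as_bool(truth, "truth")
    if p.shape != t.shape:
        raise InvalidArgumentError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)),
    )


def _scores(c: ConfusionCounts) -> SegmentationScores:
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    iou = ratio(c.tp, c.tp + c.fp + c.fn)
    accuracy = ratio(c.tp + c.tn, c.total)
    return SegmentationScores(precision, accuracy, iou, recall, degenerate)


def segmentation_metrics(pred: np.ndarray, truth: np.ndarray) -> SegmentationScores:
    """Precision, accuracy, IOU and recall of one predicted mask."""
    return _scores(confusion_counts(pred, truth))


def pooled_metrics(pairs) -> SegmentationScores:
    """Micro-averaged scores over (pred, truth) mask pairs: confusion counts
    are pooled across all frames before the ratios are taken."""
    total = ConfusionCounts(0, 0, 0, 0)
    n = 0
    for pred, truth in pairs:
        total = total + confusion_counts(pred, truth)
        n += 1
    if n == 0:
        raise InvalidArgumentError("need at least one mask pair")
    return _scores(total)


# ---------------------------------------------------------------------------
# sharpness
# ---------------------------------------------------------------------------

def _as_float_img(img: np.ndarray, min_h: int, min_w: int, name: str) -> np.ndarray:
    a = np.asarray(img, dtype=float)   # float cast avoids unsigned wraparound
    if a.ndim != 2:
        raise InvalidArgumentError(f"{name} expects a 2-D grayscale image")
    if a.shape[0] < min_h or a.shape[1] < min_w:
        raise InvalidArgumentError(
            f"{name} needs at least {min_h}x{min_w} pixels, got {a.shape}"
        )
    return a


def sharpness_brenner(img: np.ndarray) -> float:
    """Sum of squared horizontal intensity differences at offset 2."""
    a = _as_float_img(img, 1, 3, "sharpness_brenner")
    d = a[:, 2:] - a[:, :-2]
    return float(np.sum(d * d))


def sharpness_roberts(img: np.ndarray) -> float:
    """Sum of squared cross (diagonal) differences over 2x2 neighbourhoods."""
    a = _as_float_img(img, 2, 2, "sharpness_roberts")
    d1 = a[1:, 1:] - a[:-1, :-1]
    d2 = a[1:, :-1] - a[:-1, 1:]
    return float(np.sum(d1 * d1) + np.sum(d2 * d2))


def sharpness_smd2(img: np.ndarray, signed: bool = False) -> float:
    """Sum over pixels of the product of the two forward differences.

    The default multiplies absolute differences (the standard focus
    measure, guaranteed nonnegative); ``signed=True`` keeps the raw signed
    product of the literal formula.
    """
    a = _as_float_img(img, 2, 2, "sharpness_smd2")
    dv = a[:-1, :-1] - a[1:, :-1]
    dh = a[:-1, :-1] - a[:-1, 1:]
    if signed:
        return float(np.sum(dv * dh))
    return float(np.sum(np.abs(dv) * np.abs(dh)))


@dataclass(frozen=True)
class SharpnessReport:
    brenner: float
    roberts: float
    smd2: float

    def as_dict(self) -> dict:
        return {"brenner": self.brenner, "roberts": self.roberts, "smd2": self.smd2}


def sharpness_report(img: np.ndarray) -> SharpnessReport:
    return SharpnessReport(
        sharpness_brenner(img), sharpness_roberts(img), sharpness_smd2(img)
    )


def relative_difference(smaller_value: float, reference_value: float) -> float:
    """``(reference - smaller) / reference``, the drop of a quality measure
    relative to the sharper acquisition taken as the benchmark."""
    if reference_value <= 0:
        raise InvalidArgumentError("reference value must be positive")
    return (reference_value - smaller_value) / reference_value
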