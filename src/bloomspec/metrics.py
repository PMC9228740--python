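"""Segmentation evaluation and pollution-area grading.

Binary pixel counts (TP/FP/FN/TN for one positive class against the rest)
feed pixel accuracy PA = (TP+TN)/total and IoU = TP/(TP+FP+FN).  The bloom
pollution proportion is P = A1/A x 100 with A1 the bloom-pixel count and A the
total evaluated pixels; P maps onto the five-level severity scale used in
Chinese algal-bloom monitoring practice:

=====  ===============  ================================
Level  Proportion P (%) Characteristics
=====  ===============  ================================
I      P = 0            no blooms
II     0 < P < 10       no obvious blooms
III    10 <= P < 30     mild blooms
IV     30 <= P < 60     moderate blooms
V      60 <= P <= 100   severe blooms
=====  ===============  ================================

Ignore-class pixels (in either the prediction or the truth) are excluded from
every count and from both the numerator and denominator of P.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .raster_io import LabelRaster, ValidationError

__all__ = [
    "ConfusionCounts",
    "PollutionReport",
    "UndefinedMetricError",
    "confusion",
    "pixel_accuracy",
    "multiclass_pixel_accuracy",
    "iou",
    "bloom_fraction",
    "grade_level",
    "proportion_error",
    "pollution_report",
    "LEVELS",
]

#: Severity levels, lightest to heaviest.
LEVELS = ("I", "II", "III", "IV", "V")


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is empty (no evaluated pixels / empty union)."""


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Binary pixel counts for one positive class vs. the rest."""

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


@dataclasses.dataclass(frozen=True)
class PollutionReport:
    """Bloom-pixel count, evaluated-pixel count, proportion and its level."""

    bloom_pixels: int
    evaluated_pixels: int
    proportion: float  # percentage in [0, 100]
    level: str

    def to_dict(self) -> dict:
        return {
            "bloom_pixels": self.bloom_pixels,
            "evaluated_pixels": self.evaluated_pixels,
            "P": self.proportion,
            "level": self.level,
        }


def _check_compatible(pred: LabelRaster, truth: LabelRaster) -> None:
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.scheme != truth.scheme:
        raise ValidationError("prediction and truth use different class schemes")


def confusion(
    pred: LabelRaster, truth: LabelRaster, positive_class: int
) -> ConfusionCounts:
    """Binary confusion counts for ``positive_class`` vs. everything else.

    Pixels carrying the ignore class in either raster are excluded.
    """
    _check_compatible(pred, truth)
    ig = pred.scheme.ignore_index
    ok = (pred.data != ig) & (truth.data != ig)
    p = pred.data[ok] == positive_class
    t = truth.data[ok] == positive_class
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def pixel_accuracy(c: ConfusionCounts) -> float:
    """PA = (TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise UndefinedMetricError("no evaluated pixels")
    return (c.tp + c.tn) / c.total


def multiclass_pixel_accuracy(pred: LabelRaster, truth: LabelRaster) -> float:
    """Fraction of evaluated pixels whose full class label matches exactly.

    The K-class generalization (trace of the confusion matrix over its total);
    the binary PA above remains the primitive.
    """
    _check_compatible(pred, truth)
    ig = pred.scheme.ignore_index
    ok = (pred.data != ig) & (truth.data != ig)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedMetricError("no evaluated pixels")
    return float(np.sum(pred.data[ok] == truth.data[ok])) / n


def iou(c: ConfusionCounts) -> float:
    """IoU = TP / (TP + FP + FN)."""
    union = c.tp + c.fp + c.fn
    if union == 0:
        raise UndefinedMetricError("empty union: class absent from both rasters")
    return c.tp / union


def bloom_fraction(
    labels: LabelRaster,
    bloom_class: int | None = None,
    water_only: bool = False,
) -> float:
    """Pollution proportion P = bloom pixels / evaluated pixels x 100.

    With ``water_only`` the denominator is restricted to water-surface pixels
    (water + bloom classes) instead of all evaluated pixels — useful when bank
    area should not dilute the proportion.
    """
    scheme = labels.scheme
    bloom_class = scheme.bloom_index if bloom_class is None else bloom_class
    ok = labels.evaluated_mask()
    if water_only:
        ok &= (labels.data == bloom_class) | (labels.data == scheme.index("water"))
    total = int(ok.sum())
    if total == 0:
        raise UndefinedMetricError("no evaluated pixels")
    return 100.0 * int(np.sum(labels.data[ok] == bloom_class)) / total


def grade_level(p: float) -> str:
    """Severity level for a pollution proportion ``p`` in percent.

    Exactly one level fires for every value of [0, 100]; the printed interval
    boundaries are used verbatim (II open on both sides, III/IV closed-left
    open-right, V closed on both sides).
    """
    if not 0.0 <= p <= 100.0 or not np.isfinite(p):
        raise ValueError(f"proportion must lie in [0, 100], got {p}")
    if p == 0.0:
        return "I"
    if p < 10.0:
        return "II"
    if p < 30.0:
        return "III"
    if p < 60.0:
        return "IV"
    return "V"


def proportion_error(estimated_p: float, true_p: float) -> float:
    """Absolute misjudgment of the pollution proportion, in percentage points."""
    for name, v in (("estimated_p", estimated_p), ("true_p", true_p)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    return abs(estimated_p - true_p)


def pollution_report(
    labels: LabelRaster,
    bloom_class: int | None = None,
    water_only: bool = False,
) -> PollutionReport:
    """Count bloom pixels, compute P and grade it in one step."""
    scheme = labels.scheme
    bloom_class = scheme.bloom_index if bloom_class is None else bloom_class
    ok = labels.evaluated_mask()
    if water_only:
        ok &= (labels.data == bloom_class) | (labels.data == scheme.index("water"))
    total = int(ok.sum())
    if total == 0:
        raise UndefinedMetricError("no evaluated pixels")
    a1 = int(np.sum(labels.data[ok] == bloom_class))
    p = 100.0 * a1 / total
    return PollutionReport(
        bloom_pixels=a1, evaluated_pixels=total, proportion=p, level=grade_level(p)
    )
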