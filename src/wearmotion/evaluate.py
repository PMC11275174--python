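"""Confusion-matrix construction and recognition-rate arithmetic.

Per-class recognition rate is the percentage of trials of that class whose
predicted label matches the true one.  The headline *average recognition
rate* is the unweighted arithmetic mean of the per-class rates — not the
pooled accuracy — and the two differ whenever either the row totals or the
per-class rates are unequal.  Rates are reported at two decimals, rounded
half-up; internal arithmetic is kept at full precision and the mean is
taken over the unrounded per-class rates before its own rounding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import ActivityLabel
from .errors import ValidationError

__all__ = [
    "LABEL_ORDER",
    "ConfusionMatrix",
    "confusion_from_decisions",
    "recognition_rates",
    "RecognitionReport",
    "k_class_mean",
    "pooled_accuracy",
    "majority_label",
    "round_half_up",
]

#: Canonical row/column order of every confusion matrix in the package.
LABEL_ORDER: tuple[ActivityLabel, ...] = (
    ActivityLabel.STAND,
    ActivityLabel.WALK,
    ActivityLabel.JUMP,
)
_LABEL_INDEX = {label: k for k, label in enumerate(LABEL_ORDER)}


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the convention of reported rates)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 trial counts; rows are true labels, columns predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (3, 3):
            raise ValidationError(f"counts must be 3x3, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def totals(self) -> np.ndarray:
        """Per-row trial counts."""
        return self.counts.sum(axis=1)

    def row(self, label: ActivityLabel) -> np.ndarray:
        return self.counts[_LABEL_INDEX[label]]


def confusion_from_decisions(
    truth: Sequence[ActivityLabel], predicted: Sequence[ActivityLabel]
) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned truth/prediction sequences."""
    if len(truth) != len(predicted):
        raise ValidationError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted labels"
        )
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[_LABEL_INDEX[ActivityLabel(t)], _LABEL_INDEX[ActivityLabel(p)]] += 1
    return ConfusionMatrix(counts=counts)


@dataclass(frozen=True)
class RecognitionReport:
    """Per-class recognition rates (percent) and their unweighted mean.

    ``rates``/``mean`` are the reported two-decimal values; ``raw_rates``/
    ``raw_mean`` keep full precision.
    """

    raw_rates: Mapping[ActivityLabel, float]
    raw_mean: float

    @property
    def rates(self) -> dict[ActivityLabel, float]:
        return {label: round_half_up(r) for label, r in self.raw_rates.items()}

    @property
    def mean(self) -> float:
        return round_half_up(self.raw_mean)


def recognition_rates(cm: ConfusionMatrix) -> RecognitionReport:
    """Per-class rates 100·diag/total and their unweighted mean.

    Raises
    ------
    ValidationError
        If any class has zero trials.
    """
    totals = cm.totals
    if (totals == 0).any():
        empty = [LABEL_ORDER[k].value for k in np.flatnonzero(totals == 0)]
        raise ValidationError(f"classes with zero trials: {empty}")
    raw = {
        label: 100.0 * cm.counts[k, k] / totals[k] for k, label in enumerate(LABEL_ORDER)
    }
    return RecognitionReport(raw_rates=raw, raw_mean=float(np.mean(list(raw.values()))))


def k_class_mean(rates: Iterable[float]) -> float:
    """Unweighted mean of a subset of per-class rates, reported at 2 dp."""
    values = list(rates)
    if not values:
        raise ValidationError("cannot average an empty set of rates")
    return round_half_up(float(np.mean(values)))


def pooled_accuracy(cm: ConfusionMatrix) -> float:
    """Overall percent correct pooled across classes (full precision).

    Differs from the class-mean whenever row totals or rates are unequal;
    kept separate so the two are never silently conflated.
    """
    total = int(cm.counts.sum())
    if total == 0:
        raise ValidationError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / total


def majority_label(labels: Sequence[ActivityLabel]) -> ActivityLabel:
    """Majority vote over window labels; ties resolve toward stand.

    Bridges window decisions to one label per trial: a trial's prediction
    is the most frequent window label, with ties broken by the canonical
    order (stand, then walk, then jump).
    """
    if not labels:
        raise ValidationError("cannot vote over zero labels")
    counts = Counter(ActivityLabel(l) for l in labels)
    best = max(counts.values())
    for label in LABEL_ORDER:
        if counts.get(label, 0) == best:
            return label
    raise AssertionError("unreachable")  # pragma: no cover
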