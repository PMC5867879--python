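"""Confusion-count bookkeeping and the five evaluation metrics.

Counts follow Chou's notation: N+ and N- are the true class sizes, F- the
positives misclassified as negative, F+ the negatives misclassified as
positive, so TP = N+ - F-, FN = F-, TN = N- - F+, FP = F+.  The five metrics:

    Sn  = 1 - F-/N+
    Sp  = 1 - F+/N-
    Acc = 1 - (F+ + F-)/(N+ + N-)
    MCC = [1 - (F-/N+ + F+/N-)] / sqrt[(1 + (F+ - F-)/N+)(1 + (F- - F+)/N-)]
    F   = 2PR/(P + R),  P = TP/(TP + FP),  R = TP/(TP + FN)

The MCC form above is an algebraic rewriting of the standard four-marginal
Matthews correlation coefficient; the equivalence is property-tested.
``counts_from_rates`` bridges printed (Sn, Sp) percentages back to the unique
integer counts that reproduce them, which is how published result rows are
re-derived for verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InconsistentRatesError, UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts in N+/N-/F+/F- form with TP/TN/FP/FN views."""

    n_pos: int
    n_neg: int
    f_neg: int = 0
    f_pos: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "f_neg", "f_pos"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.f_neg > self.n_pos:
            raise ValidationError("F- cannot exceed N+")
        if self.f_pos > self.n_neg:
            raise ValidationError("F+ cannot exceed N-")
        if self.n_pos + self.n_neg < 1:
            raise ValidationError("confusion counts must cover at least one sample")

    @property
    def tp(self) -> int:
        return self.n_pos - self.f_neg

    @property
    def fn(self) -> int:
        return self.f_neg

    @property
    def tn(self) -> int:
        return self.n_neg - self.f_pos

    @property
    def fp(self) -> int:
        return self.f_pos

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            n_pos=self.n_pos + other.n_pos,
            n_neg=self.n_neg + other.n_neg,
            f_neg=self.f_neg + other.f_neg,
            f_pos=self.f_pos + other.f_pos,
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValidationError("y_true and y_pred must have equal length")
        return cls(
            n_pos=int((y_true == 1).sum()),
            n_neg=int((y_true == 0).sum()),
            f_neg=int(((y_true == 1) & (y_pred == 0)).sum()),
            f_pos=int(((y_true == 0) & (y_pred == 1)).sum()),
        )


def sensitivity(c: ConfusionCounts) -> float:
    """Sn = 1 - F-/N+ (recall on the positive class)."""
    if c.n_pos < 1:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    return 1.0 - c.f_neg / c.n_pos


def specificity(c: ConfusionCounts) -> float:
    """Sp = 1 - F+/N- (recall on the negative class)."""
    if c.n_neg < 1:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return 1.0 - c.f_pos / c.n_neg


def accuracy(c: ConfusionCounts) -> float:
    """Acc = 1 - (F+ + F-)/(N+ + N-)."""
    return 1.0 - (c.f_pos + c.f_neg) / (c.n_pos + c.n_neg)


def mcc_chou(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in its N+/N-/F+/F- form.

    Requires all four confusion-matrix marginals to be positive; a zero
    marginal makes the coefficient undefined and raises explicitly.
    """
    marginals = (c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn)
    if min(marginals) <= 0:
        raise UndefinedMetricError(
            f"MCC undefined: a confusion-matrix marginal is zero {marginals}"
        )
    num = 1.0 - (c.f_neg / c.n_pos + c.f_pos / c.n_neg)
    den = math.sqrt(
        (1.0 + (c.f_pos - c.f_neg) / c.n_pos)
        * (1.0 + (c.f_neg - c.f_pos) / c.n_neg)
    )
    # guard against float round-off nudging a boundary case past +-1
    return min(1.0, max(-1.0, num / den))


def f_score(c: ConfusionCounts) -> float:
    """F = 2PR/(P+R) with P = TP/(TP+FP), R = TP/(TP+FN); 0 when TP = 0."""
    if c.tp + c.fp < 1 or c.tp + c.fn < 1:
        raise UndefinedMetricError(
            "F-score undefined: precision or recall has an empty denominator"
        )
    if c.tp == 0:
        return 0.0
    p = c.tp / (c.tp + c.fp)
    r = c.tp / (c.tp + c.fn)
    return 2.0 * p * r / (p + r)


def all_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The five-metric report (fractions): Sn, Sp, Acc, MCC, F_score."""
    return {
        "Sn": sensitivity(c),
        "Sp": specificity(c),
        "Acc": accuracy(c),
        "MCC": mcc_chou(c),
        "F_score": f_score(c),
    }


def as_percent(metrics: Mapping[str, float], ndigits: int = 2) -> dict[str, float]:
    """Render fractional metrics on the percent scale at report time."""
    return {k: round(100.0 * v, ndigits) for k, v in metrics.items()}


def counts_from_rates(
    sn: float,
    sp: float,
    n_pos: int,
    n_neg: int,
    tol: float = 0.005,
) -> ConfusionCounts:
    """Back-derive integer confusion counts from printed (Sn, Sp) rates.

    F- = round(N+ (1 - Sn)) and F+ = round(N- (1 - Sp)); the rounded counts
    must reproduce the given rates to within ``tol`` (half a percent by
    default, the precision of two-decimal percentages), otherwise the rates
    are inconsistent with the stated class sizes.
    """
    if not (0.0 <= sn <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValidationError("rates must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("class sizes must be positive")
    f_neg = int(round(n_pos * (1.0 - sn)))
    f_pos = int(round(n_neg * (1.0 - sp)))
    c = ConfusionCounts(n_pos=n_pos, n_neg=n_neg, f_neg=f_neg, f_pos=f_pos)
    if abs(sensitivity(c) - sn) > tol or abs(specificity(c) - sp) > tol:
        raise InconsistentRatesError(
            f"no integer counts reproduce Sn={sn}, Sp={sp} with "
            f"N+={n_pos}, N-={n_neg} within {tol}"
        )
    return c
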