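"""Precision, Recall, F-measure, Accuracy and relative-improvement grids.

All four indexes are expressed as percentages (78 means 78%), matching how
relation-extraction results are conventionally tabulated.  Display values
round half-up to two decimals; internal values stay at full precision.
The positive class is "relation present".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "precision",
    "recall",
    "accuracy",
    "f_measure",
    "relative_improvement",
    "evaluate",
    "comparison_table",
    "round2",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (table display convention)."""
    if math.isnan(x):
        return x
    return math.floor(x * 100 + 0.5) / 100


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def correct(self) -> int:
        return self.tp + self.tn


def confusion(
    predicted: Mapping[str, int], truth: Mapping[str, int]
) -> ConfusionCounts:
    """Tally a confusion matrix over the ids present in both maps."""
    tp = fp = fn = tn = 0
    for iid, p in predicted.items():
        if iid not in truth:
            continue
        t = truth[iid]
        if p == +1:
            tp, fp = (tp + 1, fp) if t == +1 else (tp, fp + 1)
        else:
            tn, fn = (tn + 1, fn) if t == -1 else (tn, fn + 1)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _guarded(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def precision(c: ConfusionCounts) -> float:
    """tp / (tp + fp), as a percentage; NaN with a warning if undefined."""
    return _guarded(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    """tp / (tp + fn), as a percentage."""
    return _guarded(c.tp, c.tp + c.fn, "recall")


def accuracy(c: ConfusionCounts) -> float:
    """(tp + tn) / total, as a percentage."""
    return _guarded(c.tp + c.tn, c.total, "accuracy")


def f_measure(p: float, r: float) -> float:
    """Harmonic mean 2pr/(p+r) of precision and recall percentages."""
    if math.isnan(p) or math.isnan(r) or p + r == 0:
        warnings.warn("F-measure undefined", stacklevel=2)
        return float("nan")
    return 2.0 * p * r / (p + r)


def relative_improvement(a: float, b: float) -> float:
    """Percentage change of a over baseline b: 100 * (a - b) / b."""
    if b == 0:
        warnings.warn("relative improvement undefined (baseline 0)", stacklevel=2)
        return float("nan")
    return 100.0 * (a - b) / b


@dataclass(frozen=True)
class EvaluationReport:
    """One result row: correct/incorrect counts plus the four indexes (%)."""

    correct: int
    incorrect: int
    total: int
    precision: float
    recall: float
    f_measure: float
    accuracy: float

    def rounded(self) -> "EvaluationReport":
        return EvaluationReport(
            correct=self.correct,
            incorrect=self.incorrect,
            total=self.total,
            precision=round2(self.precision),
            recall=round2(self.recall),
            f_measure=round2(self.f_measure),
            accuracy=round2(self.accuracy),
        )


def evaluate(
    predicted: Mapping[str, int], truth: Mapping[str, int]
) -> EvaluationReport:
    """Score predictions against ground truth on their shared ids."""
    c = confusion(predicted, truth)
    p, r = precision(c), recall(c)
    return EvaluationReport(
        correct=c.correct,
        incorrect=c.total - c.correct,
        total=c.total,
        precision=p,
        recall=r,
        f_measure=f_measure(p, r),
        accuracy=accuracy(c),
    )


def comparison_table(
    accuracies: Mapping[str, Mapping[str, float]],
    reference: str = "LXRE",
    competitors: Sequence[str] = ("N-LXRE", "N-RE"),
) -> dict[str, dict[str, float]]:
    """Best/worst relative-improvement grid of the reference algorithm.

    ``accuracies`` maps algorithm name -> condition (e.g. variant or corpus
    size) -> accuracy %.  For each condition the reference accuracy is
    compared against the best and the worst competitor accuracy.
    """
    ref = accuracies[reference]
    out: dict[str, dict[str, float]] = {}
    for cond, a in ref.items():
        rivals = [accuracies[c][cond] for c in competitors]
        out[cond] = {
            "best": round2(relative_improvement(a, max(rivals))),
            "worst": round2(relative_improvement(a, min(rivals))),
        }
    return out
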