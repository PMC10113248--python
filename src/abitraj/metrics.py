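"""Confusion counts and the clinical performance metrics of the classifier.

The detection target is the NEGATIVE discharge outcome (the majority class:
patients who do not reach GOS >= 4), so "sensitivity" is the fraction of
true negative-outcome patients the rule flags as negative, and "specificity"
the fraction of positive-outcome patients flagged positive.  A flag flips
the convention.  Shadow/unclassified patients are excluded from every
metric; "classification ability" is the fraction of patients that received a
non-shadow prediction at all.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

from .cohort import NEGATIVE, POSITIVE
from .classifier import SHADOW, UNCLASSIFIED


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int  # predicted target class, truly target class
    fn: int
    tn: int
    fp: int
    n_shadow: int = 0
    n_unclassified: int = 0

    def classified(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class PerformanceMetrics:
    """Percentages over classified subjects; None where a denominator is 0."""

    classification_ability: float
    n_classified: int
    total_n: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def confusion(
    predictions: Mapping, truths: Mapping, target: str = NEGATIVE
) -> ConfusionCounts:
    """Tally confusion counts over classified patients.

    ``predictions`` and ``truths`` map patient ID -> label; shadow and
    unclassified predictions are excluded from the counts but tallied.
    ``target`` is the detection class (default: negative outcome).
    """
    missing = set(predictions) - set(truths)
    if missing:
        raise KeyError(f"predictions without truth labels: {sorted(map(str, missing))}")
    other = POSITIVE if target == NEGATIVE else NEGATIVE
    tp = fn = tn = fp = shadow = unclassified = 0
    for pid, pred in predictions.items():
        if pred == SHADOW:
            shadow += 1
            continue
        if pred == UNCLASSIFIED:
            unclassified += 1
            continue
        truth = truths[pid]
        if truth == target:
            tp += pred == target
            fn += pred == other
        else:
            tn += pred == other
            fp += pred == target
    return ConfusionCounts(tp, fn, tn, fp, shadow, unclassified)


def _pct(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def metrics(counts: ConfusionCounts, total_n: int) -> PerformanceMetrics:
    """Accuracy/sensitivity/specificity/PPV/NPV (percent, classified only)."""
    if min(counts.tp, counts.fn, counts.tn, counts.fp) < 0:
        raise ValueError("negative confusion counts")
    n_cls = counts.classified()
    return PerformanceMetrics(
        classification_ability=_pct(n_cls, total_n),
        n_classified=n_cls,
        total_n=total_n,
        accuracy=_pct(counts.tp + counts.tn, n_cls),
        sensitivity=_pct(counts.tp, counts.tp + counts.fn),
        specificity=_pct(counts.tn, counts.tn + counts.fp),
        ppv=_pct(counts.tp, counts.tp + counts.fp),
        npv=_pct(counts.tn, counts.tn + counts.fn),
        counts=counts,
    )
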