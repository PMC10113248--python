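"""Time-varying threshold classifier built from the two groups' bands.

Before the crossover day t* — the first day where the negative group's upper
95% limit drops below the positive group's lower 95% limit — the two bands
overlap and three regions exist:

* score above Threshold 1 (the negative band's upper limit): positive;
* score below Threshold 2 (the positive band's lower limit): negative;
* in between: the "shadow" area, where no prediction is made.

From t* on, a single cut-off applies (Threshold 3, the positive band's lower
limit): scores at or above it predict a positive outcome, below it negative.
A patient with several evaluations is classified from the earliest visit
that falls outside the shadow area (the default), so a later visit resolves
patients who were initially in shadow without overriding an earlier call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import NEGATIVE, POSITIVE
from .trajectory import TrajectoryBand

SHADOW = "shadow"
UNCLASSIFIED = "unclassified"

#: refinement precision of the crossover day, in days
T_STAR_PRECISION = 0.1


def _interp(grid: np.ndarray, values: np.ndarray, t: float) -> float:
    return float(np.interp(t, grid, values))


@dataclass
class ClassifierRule:
    """Crossover day plus the three threshold curves derived from the bands."""

    t_star: float
    band_neg: TrajectoryBand
    band_pos: TrajectoryBand
    no_separation: bool = False

    def threshold1(self, t: float) -> float:
        """Upper 95% limit of the negative-group curve (used for t < t*)."""
        return _interp(self.band_neg.grid, self.band_neg.upper, t)

    def threshold2(self, t: float) -> float:
        """Lower 95% limit of the positive-group curve (used for t < t*)."""
        return _interp(self.band_pos.grid, self.band_pos.lower, t)

    def threshold3(self, t: float) -> float:
        """Lower 95% limit of the positive-group curve (used for t >= t*)."""
        return _interp(self.band_pos.grid, self.band_pos.lower, t)


@dataclass(frozen=True)
class Prediction:
    patient_id: object
    label: str  # positive | negative | shadow | unclassified
    evaluation_used: str | None = None
    time: float | None = None
    score: float | None = None


def find_crossover(band_neg: TrajectoryBand, band_pos: TrajectoryBand) -> ClassifierRule:
    """Locate t*, the first time the two 95% bands separate.

    t* is the smallest grid time where upper_neg(t) <= lower_pos(t), refined
    by bisection between the bracketing grid points to 0.1-day precision.  If
    the bands never separate on the grid, t* is the grid end and the rule is
    flagged ``no_separation``.
    """
    if band_neg.grid.shape != band_pos.grid.shape or not np.allclose(
        band_neg.grid, band_pos.grid
    ):
        raise ValueError("bands must share the same time grid")
    gap = band_pos.lower - band_neg.upper  # >= 0 means separated
    sep = np.nonzero(gap >= 0)[0]
    if len(sep) == 0:
        return ClassifierRule(
            float(band_neg.grid[-1]), band_neg, band_pos, no_separation=True
        )
    i = int(sep[0])
    if i == 0:
        return ClassifierRule(float(band_neg.grid[0]), band_neg, band_pos)

    lo, hi = float(band_neg.grid[i - 1]), float(band_neg.grid[i])

    def g(t: float) -> float:
        return _interp(band_pos.grid, band_pos.lower, t) - _interp(
            band_neg.grid, band_neg.upper, t
        )

    while hi - lo > T_STAR_PRECISION:
        mid = 0.5 * (lo + hi)
        if g(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return ClassifierRule(hi, band_neg, band_pos)


def classify_point(rule: ClassifierRule, t: float, score: float) -> str:
    """Label one (time, score) observation.

    Before t*: strictly above Threshold 1 is positive, strictly below
    Threshold 2 is negative, anything else (including exact ties) is shadow.
    From t* on: at or above Threshold 3 is positive, below it negative — no
    shadow is possible.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    if t < rule.t_star:
        if score > rule.threshold1(t):
            return POSITIVE
        if score < rule.threshold2(t):
            return NEGATIVE
        return SHADOW
    return POSITIVE if score >= rule.threshold3(t) else NEGATIVE


def classify_patient(
    rule: ClassifierRule,
    evaluations: Sequence[tuple],
    combine: str = "earliest",
    patient_id: object = None,
) -> Prediction:
    """Combine a patient's visits into one prediction.

    ``evaluations`` is a time-ordered sequence of (t, score) or
    (t, score, label) tuples.  ``combine='earliest'`` (default) returns the
    first visit whose point label is not shadow; if every visit is in shadow
    or none is available, the patient is shadow/unclassified respectively.
    ``combine='latest'`` uses only the last available visit.
    """
    evals = [
        e for e in evaluations if e[1] is not None and np.isfinite(e[1])
    ]
    if not evals:
        return Prediction(patient_id, UNCLASSIFIED)
    evals = sorted(evals, key=lambda e: e[0])
    if combine == "latest":
        evals = [evals[-1]]
    elif combine != "earliest":
        raise ValueError("combine must be 'earliest' or 'latest'")
    for e in evals:
        t, score = float(e[0]), float(e[1])
        name = e[2] if len(e) > 2 else None
        label = classify_point(rule, t, score)
        if label != SHADOW:
            return Prediction(patient_id, label, name, t, score)
    t, score = float(evals[0][0]), float(evals[0][1])
    name = evals[0][2] if len(evals[0]) > 2 else None
    return Prediction(patient_id, SHADOW, name, t, score)
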