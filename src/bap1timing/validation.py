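"""Volume-based BAP1-expression classification and its scoring.

A fitted percent-lost curve is turned into a classifier of immunohistochemical
BAP1 grade: predicted percent of BAP1-POSITIVE cells is the complement of the
fitted percent lost (clamped to [0, 100]), and a tumor is called "high"
expression when that percent is at or above a cutoff (33% by convention in
uveal-melanoma IHC grading). Predictions are scored against pathologist labels
with the standard 2x2 metrics and Cohen's kappa, banded per Landis & Koch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import CurveFit, evaluate
from .errors import InvalidInputError

DEFAULT_CUTOFF_PERCENT = 33.0

LOW, HIGH = "low", "high"


def predict_class(fit: CurveFit, volume: float, cutoff: float = DEFAULT_CUTOFF_PERCENT) -> str:
    """Predict low/high BAP1 expression from tumor volume.

    percent-positive = 100 - clamp(fitted percent lost, 0, 100); class is
    "high" iff percent-positive >= cutoff (ties go to "high").
    """
    lost = float(np.clip(evaluate(fit, volume), 0.0, 100.0))
    positive = 100.0 - lost
    return HIGH if positive >= cutoff else LOW


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 agreement between volume-predicted and pathologist BAP1 grade.

    "high" is the positive class. ``kappa`` is None when the marginals are
    degenerate (expected agreement 1) and chance correction is undefined.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float | None
    band: str

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def kappa_band(kappa: float | None) -> str:
    """Landis-Koch qualitative band for a kappa value."""
    if kappa is None:
        return "undefined"
    if kappa <= 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def score_predictions(pairs) -> ConfusionSummary:
    """Score (predicted, observed) class pairs; both in {"low", "high"}."""
    pairs = list(pairs)
    if not pairs:
        raise InvalidInputError("no prediction pairs to score")
    for p, o in pairs:
        if p not in (LOW, HIGH) or o not in (LOW, HIGH):
            raise InvalidInputError(f"classes must be 'low'/'high', got ({p!r}, {o!r})")
    tp = sum(1 for p, o in pairs if p == HIGH and o == HIGH)
    fp = sum(1 for p, o in pairs if p == HIGH and o == LOW)
    fn = sum(1 for p, o in pairs if p == LOW and o == HIGH)
    tn = sum(1 for p, o in pairs if p == LOW and o == LOW)
    n = len(pairs)
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    # chance-corrected agreement from the marginal products
    p_o = accuracy
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = None if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return ConfusionSummary(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        kappa=kappa,
        band=kappa_band(kappa),
    )


def validate_curve(
    fit: CurveFit,
    volumes,
    pathologist_classes,
    cutoff: float = DEFAULT_CUTOFF_PERCENT,
) -> ConfusionSummary:
    """Predict classes from volumes via ``fit`` and score against labels."""
    preds = [predict_class(fit, v, cutoff) for v in volumes]
    return score_predictions(list(zip(preds, pathologist_classes)))
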