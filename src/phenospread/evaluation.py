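"""Scoring phenotype predictions against gold labels.

Standard 2x2 confusion counts and the four headline metrics: precision
tp/(tp+fp), recall tp/(tp+fn), F1 (harmonic mean of the two), accuracy
(tp+tn)/total. Undefined metrics (zero denominators) come back as 0
with a logged warning rather than an exception, so threshold sweeps
never crash on degenerate operating points.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .errors import ValidationError
from .types import ConfusionMatrix, EvaluationMetrics, GoldLabels, PredictionResult

logger = logging.getLogger(__name__)

__all__ = ["confusion", "metrics", "harmonic_f1", "percent", "format_percent"]


def confusion(preds: Sequence[PredictionResult], gold: GoldLabels) -> ConfusionMatrix:
    """Count tp/fp/tn/fn; every predicted patient must have a gold label."""
    missing = sorted({p.patient_id for p in preds} - set(gold))
    if missing:
        raise ValidationError(f"patients without gold labels: {missing}")
    tp = fp = tn = fn = 0
    for p in preds:
        truth = gold[p.patient_id]
        if p.label and truth:
            tp += 1
        elif p.label and not truth:
            fp += 1
        elif not p.label and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2pr/(p+r); 0 when both components are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> EvaluationMetrics:
    if cm.total == 0:
        raise ValidationError("cannot compute metrics of an all-zero confusion matrix")
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        logger.warning("no positive predictions; precision defined as 0")
        precision = 0.0
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        logger.warning("no positive gold labels; recall defined as 0")
        recall = 0.0
    return EvaluationMetrics(
        precision=precision,
        recall=recall,
        f1=harmonic_f1(precision, recall),
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


def percent(x: float, decimals: int = 1) -> float:
    """100*x rounded half-away-from-zero to ``decimals`` places (report style)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(100.0 * x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float, decimals: int = 1) -> str:
    return f"{percent(x, decimals):.{decimals}f}"
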