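"""Evaluation of all-prediction and high-confidence cohorts.

AUROC uses the rank/midrank (probabilistic) convention: the probability
that a random positive outranks a random negative, with ties counting
one half.  Confusion metrics dichotomise at a supplied prediction
threshold ``theta_pred`` with "predicted positive iff prediction >=
theta_pred".  Cohorts with a single class (or no items) report ``None``
for the affected metrics instead of raising, because tiny low-confidence
cohorts are common and must still appear in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .aggregation import SlideResult
from .errors import DegenerateLabelsError, EmptyInputError, StateError

Level = Literal["tile", "slide", "patient"]
Cohort = Literal["all", "high_confidence", "low_confidence"]


@dataclass
class EvalReport:
    level: Level
    cohort: Cohort
    n_items: int
    auroc: Optional[float]
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    youden_j: Optional[float]
    theta_pred_used: float
    pct_high_confidence: Optional[float] = None  # populated on the all-cohort report

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Midrank AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise EmptyInputError("scores and labels differ in length")
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("AUROC needs both classes present")
    ranks = rankdata(s)  # midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(
    predictions: Sequence[float], labels: Sequence[int], theta_pred: float
) -> dict[str, Optional[float]]:
    """2x2-table metrics at the cutoff ``prediction >= theta_pred``.

    An absent class yields ``None`` for the metric that conditions on it
    (sensitivity without positives, specificity without negatives);
    Youden's J is ``None`` whenever either input metric is.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size == 0:
        raise EmptyInputError("confusion_metrics received no predictions")
    pred_pos = p >= theta_pred
    tp = int(np.sum(pred_pos & (y == 1)))
    tn = int(np.sum(~pred_pos & (y == 0)))
    fp = int(np.sum(pred_pos & (y == 0)))
    fn = int(np.sum(~pred_pos & (y == 1)))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    acc = (tp + tn) / p.size
    j = sens + spec - 1.0 if sens is not None and spec is not None else None
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "youden_j": j,
    }


def single_cohort_report(
    level: Level,
    cohort: Cohort,
    predictions: np.ndarray,
    labels: np.ndarray,
    theta_pred: float,
) -> EvalReport:
    if predictions.size == 0:
        return EvalReport(
            level=level, cohort=cohort, n_items=0, auroc=None, accuracy=None,
            sensitivity=None, specificity=None, youden_j=None,
            theta_pred_used=theta_pred,
        )
    try:
        a = auroc(predictions, labels)
    except DegenerateLabelsError:
        a = None
    cm = confusion_metrics(predictions, labels, theta_pred)
    return EvalReport(
        level=level,
        cohort=cohort,
        n_items=int(predictions.size),
        auroc=a,
        accuracy=cm["accuracy"],
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        youden_j=cm["youden_j"],
        theta_pred_used=theta_pred,
    )


def cohort_report(
    slide_results: Sequence[SlideResult],
    theta_pred: float,
    level: Level = "slide",
) -> list[EvalReport]:
    """Evaluate the all / high-confidence / low-confidence cohorts.

    Every slide must carry an assigned confidence.  The all-cohort
    report additionally records the percentage of items that are
    high-confidence.
    """
    if not slide_results:
        raise EmptyInputError("cohort_report received no results")
    for s in slide_results:
        if s.confidence == "unset":
            raise StateError(f"slide {s.slide_id!r} has unset confidence")
    preds = np.array([s.slide_prediction for s in slide_results])
    labels = np.array([s.label for s in slide_results])
    high = np.array([s.confidence == "high" for s in slide_results])

    all_rep = single_cohort_report(level, "all", preds, labels, theta_pred)
    all_rep.pct_high_confidence = float(100.0 * high.mean())
    high_rep = single_cohort_report(level, "high_confidence", preds[high], labels[high], theta_pred)
    low_rep = single_cohort_report(level, "low_confidence", preds[~high], labels[~high], theta_pred)
    return [all_rep, high_rep, low_rep]


def reports_to_records(reports: Sequence[EvalReport]) -> list[dict]:
    return [r.to_dict() for r in reports]
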