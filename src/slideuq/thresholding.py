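"""Youden-index threshold searches and binary confidence assignment.

Uncertainty thresholding treats the uncertainty value as a *diagnostic
test for misprediction*: an item is "flagged" when its uncertainty is at
or above a candidate threshold ``t``.  Sensitivity is the fraction of
mispredicted items flagged, specificity the fraction of correct items
not flagged, and the operating point is the ``t`` maximising Youden's
index ``J = Se + Sp - 1``.  Items whose uncertainty falls *strictly
below* the chosen threshold are high-confidence; ties with the threshold
are low-confidence.

"All possible thresholds" is realised as the finite set of midpoints
between consecutive distinct observed values, plus one candidate below
the minimum and one above the maximum; scanning the continuum cannot do
better because Se/Sp are step functions of ``t`` that only change at
observed values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ensembles import TileResult
from .errors import DegenerateLabelsError, ShapeError, StateError

HIGH_CONF_ALL = math.inf  #: sentinel threshold: everything high-confidence
LOW_CONF_ALL = -math.inf  #: sentinel threshold: everything low-confidence


@dataclass
class ThresholdSearchResult:
    """Full audit trail of one Youden cutpoint search."""

    candidates: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    j: np.ndarray
    optimum: float
    j_max: float
    degenerate: Optional[str] = None

    @property
    def is_degenerate(self) -> bool:
        return self.degenerate is not None


@dataclass
class ThresholdSet:
    """The three operating thresholds with per-fold provenance.

    ``theta_tile`` / ``theta_slide`` bound tile- and slide-level
    uncertainty; ``theta_pred`` is the slide-prediction cutoff.  When
    derived by nested cross-validation, ``theta_tile`` is the minimum of
    the per-inner-fold values and ``theta_slide`` the maximum.
    """

    theta_tile: float
    theta_slide: float
    theta_pred: float = 0.5
    inner_fold_theta_tile: list[float] = field(default_factory=list)
    inner_fold_theta_slide: list[float] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(v: float) -> object:
            if v == math.inf:
                return "inf"
            if v == -math.inf:
                return "-inf"
            return v

        payload = {
            "theta_tile": enc(self.theta_tile),
            "theta_slide": enc(self.theta_slide),
            "theta_pred": enc(self.theta_pred),
            "inner_fold_theta_tile": [enc(v) for v in self.inner_fold_theta_tile],
            "inner_fold_theta_slide": [enc(v) for v in self.inner_fold_theta_slide],
            "provenance": self.provenance,
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ThresholdSet":
        def dec(v: object) -> float:
            if v == "inf":
                return math.inf
            if v == "-inf":
                return -math.inf
            return float(v)  # type: ignore[arg-type]

        raw = json.loads(text)
        return cls(
            theta_tile=dec(raw["theta_tile"]),
            theta_slide=dec(raw["theta_slide"]),
            theta_pred=dec(raw["theta_pred"]),
            inner_fold_theta_tile=[dec(v) for v in raw.get("inner_fold_theta_tile", [])],
            inner_fold_theta_slide=[dec(v) for v in raw.get("inner_fold_theta_slide", [])],
            provenance=raw.get("provenance", {}),
        )


def _candidate_grid(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values plus one candidate
    below the minimum and one above the maximum.

    The outer candidates are placed multiplicatively (``min/2``,
    ``max*1.5``) when sign allows, so that rescaling the data rescales
    every candidate; an additive offset of 1 is the fallback at zero.
    """
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    lo = distinct[0] / 2.0 if distinct[0] > 0 else distinct[0] - 1.0
    hi = distinct[-1] * 1.5 if distinct[-1] > 0 else distinct[-1] + 1.0
    return np.concatenate(([lo], mids, [hi]))


def _search(values: np.ndarray, positive: np.ndarray) -> ThresholdSearchResult:
    """Core scan: flag item when ``value >= t``; positives should be
    flagged (Se), negatives unflagged (Sp)."""
    cands = _candidate_grid(values)
    pos_sorted = np.sort(values[positive])
    neg_sorted = np.sort(values[~positive])
    n_pos, n_neg = pos_sorted.size, neg_sorted.size
    # count(value >= t) via searchsorted on the left side
    se = (n_pos - np.searchsorted(pos_sorted, cands, side="left")) / n_pos
    sp = np.searchsorted(neg_sorted, cands, side="left") / n_neg
    j = se + sp - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximiser
    return ThresholdSearchResult(
        candidates=cands,
        se=se,
        sp=sp,
        j=j,
        optimum=float(cands[best]),
        j_max=float(j[best]),
    )


def youden_uncertainty_search(
    uncertainties: Sequence[float], correct: Sequence[bool]
) -> ThresholdSearchResult:
    """Find the uncertainty threshold that best separates mispredicted
    from correct items.

    Se(t) = fraction of incorrect items with uncertainty >= t;
    Sp(t) = fraction of correct items with uncertainty < t.  Among
    equal-J candidates the smallest is returned (more abstention).
    Degenerate inputs do not raise: with no mispredictions the result
    carries ``optimum = +inf`` (everything high-confidence), with no
    correct items ``optimum = -inf``.
    """
    u = np.asarray(uncertainties, dtype=float)
    c = np.asarray(correct, dtype=bool)
    if u.shape != c.shape:
        raise ShapeError(
            f"uncertainties ({u.shape}) and correct ({c.shape}) differ in length"
        )
    if u.size < 1:
        raise ShapeError("need at least one item")
    if not np.all(np.isfinite(u)) or u.min() < 0:
        raise ShapeError("uncertainties must be finite and non-negative")
    incorrect = ~c
    if not incorrect.any():
        empty = np.array([])
        return ThresholdSearchResult(
            candidates=empty, se=empty, sp=empty, j=empty,
            optimum=HIGH_CONF_ALL, j_max=float("nan"),
            degenerate="no mispredicted items; everything high-confidence",
        )
    if not c.any():
        empty = np.array([])
        return ThresholdSearchResult(
            candidates=empty, se=empty, sp=empty, j=empty,
            optimum=LOW_CONF_ALL, j_max=float("nan"),
            degenerate="no correct items; everything low-confidence",
        )
    return _search(u, positive=incorrect)


def prediction_threshold_search(
    slide_predictions: Sequence[float], labels: Sequence[int]
) -> ThresholdSearchResult:
    """Standard ROC Youden optimum for classifying label 1 by
    ``prediction >= t``; returns the slide prediction cutoff theta_pred."""
    p = np.asarray(slide_predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ShapeError(
            f"predictions ({p.shape}) and labels ({y.shape}) differ in length"
        )
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError(
            "prediction threshold search needs both classes present"
        )
    return _search(p, positive=(y == 1))


def assign_tile_confidence(
    tiles: Sequence[TileResult], theta_tile: float
) -> list[TileResult]:
    """Flag each tile high-confidence iff ``sigma_hat < theta_tile``."""
    out = []
    for t in tiles:
        if t.sigma_hat is None or not math.isfinite(t.sigma_hat):
            raise StateError(f"tile {t.tile_id!r} has no valid sigma_hat")
        out.append(t.with_confidence("high" if t.sigma_hat < theta_tile else "low"))
    return out
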