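"""Slide- and patient-level aggregation of tile results.

With uncertainty quantification, a slide's uncertainty is the mean
``sigma_hat`` over its *high-confidence* tiles and its prediction the
mean ``mu_hat`` over the same tile set.  A slide with zero
high-confidence tiles has an undefined mean; such slides fall back to
the all-tile mean prediction, get infinite uncertainty, and are forced
low-confidence (the clinical "abstain" semantics) with
``fallback_used`` set so callers can audit them.

The non-UQ baseline simply averages every tile's prediction.

Patients are aggregated by pooling all their tiles into one
"super-slide" (unweighted by slide), then applying the slide machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .ensembles import Confidence, TileResult
from .errors import EmptyInputError, IntegrityError, StateError
from .thresholding import assign_tile_confidence


@dataclass
class SlideResult:
    slide_id: str
    patient_id: str
    label: int
    slide_uncertainty: Optional[float]  # None = unset (non-UQ); +inf = fallback
    slide_prediction: float
    n_tiles: int
    n_high_conf_tiles: int
    confidence: Confidence = "unset"
    fallback_used: bool = False

    def with_confidence(self, confidence: Confidence) -> "SlideResult":
        return replace(self, confidence=confidence)


@dataclass
class PatientResult:
    patient_id: str
    label: int
    patient_prediction: float
    patient_uncertainty: Optional[float]
    confidence: Confidence
    n_slides: int
    n_tiles: int = 0
    n_high_conf_tiles: int = 0
    fallback_used: bool = False


def _check_single_slide(tiles: Sequence[TileResult]) -> None:
    if not tiles:
        raise EmptyInputError("slide aggregation received no tiles")
    slide_ids = {t.slide_id for t in tiles}
    if len(slide_ids) != 1:
        raise IntegrityError(f"tiles span multiple slides: {sorted(slide_ids)}")


def aggregate_slide_uq(
    tiles: Sequence[TileResult], theta_tile: float
) -> SlideResult:
    """UQ slide aggregation: mean uncertainty and prediction over the
    high-confidence tiles (``sigma_hat < theta_tile``)."""
    _check_single_slide(tiles)
    flagged = assign_tile_confidence(tiles, theta_tile)
    high = [t for t in flagged if t.confidence == "high"]
    first = tiles[0]
    if high:
        return SlideResult(
            slide_id=first.slide_id,
            patient_id=first.patient_id,
            label=first.label,
            slide_uncertainty=float(np.mean([t.sigma_hat for t in high])),
            slide_prediction=float(np.mean([t.mu_hat for t in high])),
            n_tiles=len(tiles),
            n_high_conf_tiles=len(high),
        )
    return SlideResult(
        slide_id=first.slide_id,
        patient_id=first.patient_id,
        label=first.label,
        slide_uncertainty=math.inf,
        slide_prediction=float(np.mean([t.mu_hat for t in tiles])),
        n_tiles=len(tiles),
        n_high_conf_tiles=0,
        confidence="low",
        fallback_used=True,
    )


def aggregate_slide_nonuq(tiles: Sequence[TileResult]) -> SlideResult:
    """Baseline aggregation without uncertainty: all-tile mean prediction."""
    _check_single_slide(tiles)
    first = tiles[0]
    return SlideResult(
        slide_id=first.slide_id,
        patient_id=first.patient_id,
        label=first.label,
        slide_uncertainty=None,
        slide_prediction=float(np.mean([t.mu_hat for t in tiles])),
        n_tiles=len(tiles),
        n_high_conf_tiles=0,
        confidence="unset",
    )


def assign_slide_confidence(
    slides: Sequence[SlideResult], theta_slide: float
) -> list[SlideResult]:
    """Flag each slide high-confidence iff its uncertainty is strictly
    below ``theta_slide``; fallback slides (infinite uncertainty) are
    always low-confidence under any finite threshold."""
    out = []
    for s in slides:
        if s.slide_uncertainty is None:
            raise StateError(
                f"slide {s.slide_id!r} has unset uncertainty (non-UQ aggregation?)"
            )
        out.append(
            s.with_confidence(
                "high" if s.slide_uncertainty < theta_slide else "low"
            )
        )
    return out


def aggregate_patient(
    tiles: Sequence[TileResult],
    theta_tile: float = math.inf,
    mode: Literal["uq", "nonuq"] = "uq",
) -> PatientResult:
    """Pool one patient's tiles across slides and aggregate as a single
    super-slide (tiles, not slides, are the pooling unit)."""
    if not tiles:
        raise EmptyInputError("patient aggregation received no tiles")
    patient_ids = {t.patient_id for t in tiles}
    if len(patient_ids) != 1:
        raise IntegrityError(f"tiles span multiple patients: {sorted(patient_ids)}")
    n_slides = len({t.slide_id for t in tiles})
    pooled = [replace(t, slide_id="__pooled__") for t in tiles]
    if mode == "uq":
        s = aggregate_slide_uq(pooled, theta_tile)
    elif mode == "nonuq":
        s = aggregate_slide_nonuq(pooled)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PatientResult(
        patient_id=tiles[0].patient_id,
        label=tiles[0].label,
        patient_prediction=s.slide_prediction,
        patient_uncertainty=s.slide_uncertainty,
        confidence=s.confidence,
        n_slides=n_slides,
        n_tiles=s.n_tiles,
        n_high_conf_tiles=s.n_high_conf_tiles,
        fallback_used=s.fallback_used,
    )


def group_tiles_by_slide(
    tiles: Sequence[TileResult],
) -> dict[str, list[TileResult]]:
    groups: dict[str, list[TileResult]] = {}
    for t in tiles:
        groups.setdefault(t.slide_id, []).append(t)
    return groups


def aggregate_slides_uq(
    tiles: Sequence[TileResult], theta_tile: float
) -> list[SlideResult]:
    """Aggregate every slide present in ``tiles`` (sorted by slide_id)."""
    groups = group_tiles_by_slide(tiles)
    return [aggregate_slide_uq(groups[s], theta_tile) for s in sorted(groups)]


def aggregate_slides_nonuq(tiles: Sequence[TileResult]) -> list[SlideResult]:
    groups = group_tiles_by_slide(tiles)
    return [aggregate_slide_nonuq(groups[s]) for s in sorted(groups)]


def slides_to_frame(slides: Sequence[SlideResult]) -> pd.DataFrame:
    """Tidy one-row-per-slide table (the on-disk result schema)."""
    return pd.DataFrame(
        {
            "slide_id": [s.slide_id for s in slides],
            "patient_id": [s.patient_id for s in slides],
            "label": [s.label for s in slides],
            "prediction": [s.slide_prediction for s in slides],
            "uncertainty": [
                s.slide_uncertainty if s.slide_uncertainty is not None else np.nan
                for s in slides
            ],
            "confidence": [s.confidence for s in slides],
            "n_tiles": [s.n_tiles for s in slides],
            "n_high_conf_tiles": [s.n_high_conf_tiles for s in slides],
            "fallback_used": [s.fallback_used for s in slides],
        }
    )


def patients_to_frame(patients: Sequence[PatientResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "label": [p.label for p in patients],
            "prediction": [p.patient_prediction for p in patients],
            "uncertainty": [
                p.patient_uncertainty if p.patient_uncertainty is not None else np.nan
                for p in patients
            ],
            "confidence": [p.confidence for p in patients],
            "n_slides": [p.n_slides for p in patients],
            "n_tiles": [p.n_tiles for p in patients],
            "n_high_conf_tiles": [p.n_high_conf_tiles for p in patients],
            "fallback_used": [p.fallback_used for p in patients],
        }
    )
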