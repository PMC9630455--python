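"""Model/Results front-end over the thresholding machinery.

``UncertaintyThresholdModel`` is built from per-tile ensemble estimates
(with ground-truth labels) and ``fit()`` estimates the three operating
thresholds — tile uncertainty, slide uncertainty, slide prediction —
returning a ``ThresholdResults`` object that carries the estimates,
their per-fold provenance, the full Youden search curves as
diagnostics, and a ``summary()`` table; ``apply`` and ``evaluate``
project new data through the fitted thresholds.

Two fitting strategies are offered.  ``method="direct"`` runs the
Youden searches once on all supplied tiles (appropriate when the data
is itself a held-out validation set).  ``method="nested"`` partitions
the slides into inner folds, searches per fold, and combines as
min (tile) / max (slide) — the leakage-resistant protocol — reusing
the supplied ensembles rather than refitting a predictor per fold; the
fully refitting variant lives in :mod:`slideuq.nested_cv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd

from .aggregation import (
    SlideResult,
    aggregate_slides_uq,
    assign_slide_confidence,
)
from .ensembles import TileEnsemble, TileResult, estimate_all
from .errors import DegenerateLabelsError, EmptyInputError
from .metrics import EvalReport, cohort_report
from .nested_cv import _slide_search_inputs, make_fold_plan
from .thresholding import (
    HIGH_CONF_ALL,
    ThresholdSearchResult,
    ThresholdSet,
    prediction_threshold_search,
    youden_uncertainty_search,
)


class UncertaintyThresholdModel:
    """Estimates confidence thresholds from labelled tile ensembles."""

    def __init__(self, tile_results: Sequence[TileResult]):
        if not tile_results:
            raise EmptyInputError("model needs at least one tile result")
        self.tile_results = list(tile_results)

    @classmethod
    def from_ensembles(
        cls, ensembles: Sequence[TileEnsemble]
    ) -> "UncertaintyThresholdModel":
        return cls(estimate_all(ensembles))

    def _manifest(self) -> pd.DataFrame:
        rows = {}
        for t in self.tile_results:
            rows[t.slide_id] = (t.slide_id, t.patient_id, t.label)
        return pd.DataFrame(
            rows.values(), columns=["slide_id", "patient_id", "label"]
        )

    def fit(
        self,
        method: Literal["direct", "nested"] = "direct",
        k_inner: int = 5,
        seed: int = 0,
    ) -> "ThresholdResults":
        warnings: list[str] = []
        tile_searches: list[ThresholdSearchResult] = []
        slide_searches: list[ThresholdSearchResult] = []

        if method == "direct":
            groups = [self.tile_results]
        elif method == "nested":
            # split all slides directly into k_inner folds by reusing
            # the (outer) stratified-grouped fold machinery
            plan = make_fold_plan(
                self._manifest(), k_outer=k_inner, k_inner=2, seed=seed,
                group_by_patient=True,
            )
            by_fold: dict[int, list[TileResult]] = {}
            for t in self.tile_results:
                by_fold.setdefault(plan.outer_assignments[t.slide_id], []).append(t)
            groups = [by_fold[f] for f in sorted(by_fold)]
        else:
            raise ValueError(f"unknown fit method {method!r}")

        theta_tiles: list[float] = []
        theta_slides: list[float] = []
        for tiles in groups:
            ts = youden_uncertainty_search(
                [t.sigma_hat for t in tiles], [t.correct for t in tiles]
            )
            tile_searches.append(ts)
            if ts.is_degenerate:
                warnings.append(f"tile search: {ts.degenerate}")
            else:
                theta_tiles.append(ts.optimum)
            slides = aggregate_slides_uq(tiles, ts.optimum)
            u, correct = _slide_search_inputs(slides)
            ss = youden_uncertainty_search(u, correct)
            slide_searches.append(ss)
            if ss.is_degenerate:
                warnings.append(f"slide search: {ss.degenerate}")
            else:
                theta_slides.append(ss.optimum)

        theta_tile = min(theta_tiles) if theta_tiles else HIGH_CONF_ALL
        theta_slide = max(theta_slides) if theta_slides else HIGH_CONF_ALL
        if not theta_tiles:
            warnings.append("all tile searches degenerate; theta_tile = +inf")
        if not theta_slides:
            warnings.append("all slide searches degenerate; theta_slide = +inf")

        all_slides = aggregate_slides_uq(self.tile_results, theta_tile)
        try:
            pred_search: Optional[ThresholdSearchResult] = (
                prediction_threshold_search(
                    [s.slide_prediction for s in all_slides],
                    [s.label for s in all_slides],
                )
            )
            theta_pred = pred_search.optimum
        except DegenerateLabelsError:
            pred_search = None
            theta_pred = 0.5
            warnings.append("single-class slides; theta_pred defaults to 0.5")

        thresholds = ThresholdSet(
            theta_tile=theta_tile,
            theta_slide=theta_slide,
            theta_pred=theta_pred,
            inner_fold_theta_tile=[s.optimum for s in tile_searches]
            if method == "nested" else [],
            inner_fold_theta_slide=[s.optimum for s in slide_searches]
            if method == "nested" else [],
            provenance={"method": method, "seed": seed, "k_inner": k_inner},
        )
        return ThresholdResults(
            model=self,
            thresholds=thresholds,
            tile_searches=tile_searches,
            slide_searches=slide_searches,
            pred_search=pred_search,
            warnings=warnings,
        )


@dataclass
class ThresholdResults:
    """Fitted thresholds with search diagnostics."""

    model: UncertaintyThresholdModel
    thresholds: ThresholdSet
    tile_searches: list[ThresholdSearchResult]
    slide_searches: list[ThresholdSearchResult]
    pred_search: Optional[ThresholdSearchResult]
    warnings: list[str] = field(default_factory=list)

    def apply(
        self, tile_results: Optional[Sequence[TileResult]] = None
    ) -> list[SlideResult]:
        """Aggregate tiles into slides and assign confidence under the
        fitted thresholds (defaults to the training tiles)."""
        tiles = list(tile_results) if tile_results is not None else self.model.tile_results
        slides = aggregate_slides_uq(tiles, self.thresholds.theta_tile)
        return assign_slide_confidence(slides, self.thresholds.theta_slide)

    def evaluate(
        self, tile_results: Optional[Sequence[TileResult]] = None
    ) -> list[EvalReport]:
        return cohort_report(self.apply(tile_results), self.thresholds.theta_pred)

    def summary(self) -> str:
        t = self.thresholds
        lines = [
            "Uncertainty Threshold Results",
            "=" * 46,
            f"{'theta_tile (tile uncertainty)':<34}{t.theta_tile:>12.6g}",
            f"{'theta_slide (slide uncertainty)':<34}{t.theta_slide:>12.6g}",
            f"{'theta_pred (prediction cutoff)':<34}{t.theta_pred:>12.6g}",
        ]
        if t.inner_fold_theta_tile:
            lines.append("-" * 46)
            lines.append(
                "inner-fold theta_tile:  "
                + ", ".join(f"{v:.4g}" for v in t.inner_fold_theta_tile)
            )
            lines.append(
                "inner-fold theta_slide: "
                + ", ".join(f"{v:.4g}" for v in t.inner_fold_theta_slide)
            )
        js = [s.j_max for s in self.tile_searches if not s.is_degenerate]
        if js:
            lines.append("-" * 46)
            lines.append(f"{'tile-search max Youden J':<34}{max(js):>12.4f}")
        sjs = [s.j_max for s in self.slide_searches if not s.is_degenerate]
        if sjs:
            lines.append(f"{'slide-search max Youden J':<34}{max(sjs):>12.4f}")
        lines.append(f"{'n tiles':<34}{len(self.model.tile_results):>12d}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)
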