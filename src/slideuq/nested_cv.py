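"""Leakage-free uncertainty-threshold determination via nested
cross-validation, and the full cross-validated experiment runner.

Uncertainty thresholds require ground-truth labels to compute, so
deriving them on validation data would leak label information into the
selective-classification step.  Instead, each outer training set is
split into ``k_inner`` inner folds; a fresh predictor is fitted on each
inner training set and evaluated on the inner validation set, yielding
one tile threshold and one slide threshold per inner fold.  The
combined tile threshold is the *minimum* across folds and the combined
slide threshold the *maximum* — conservative at both levels.  Outer
validation tiles are never visible to any threshold computation.

Inner folds on easy data can be degenerate (no mispredicted tiles, or
no mispredicted slides); such folds are excluded from the min/max with
a recorded warning rather than aborting, and if every fold is
degenerate the combined threshold falls back to the +inf sentinel
(everything high-confidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .aggregation import (
    SlideResult,
    aggregate_slides_nonuq,
    aggregate_slides_uq,
    assign_slide_confidence,
    slides_to_frame,
)
from .ensembles import TileEnsemble, estimate_all
from .errors import ConfigError, InsufficientDataError
from .metrics import EvalReport, cohort_report, single_cohort_report
from .thresholding import (
    HIGH_CONF_ALL,
    ThresholdSearchResult,
    ThresholdSet,
    prediction_threshold_search,
    youden_uncertainty_search,
)


class PredictorContract(Protocol):
    """Minimal contract a predictor must satisfy for nested CV.

    ``fit`` receives the training tiles' identifiers (labels are
    resolvable through the dataset); ``predict_ensemble`` maps tile ids
    to forward-pass ensembles and must be deterministic given the
    predictor's own seed.  It never sees validation labels.
    """

    def fit(self, train_tile_ids: Sequence[str]) -> "PredictorContract": ...

    def predict_ensemble(self, tile_ids: Sequence[str]) -> list[TileEnsemble]: ...


def _child_seed(seed: int, *keys: int) -> int:
    """Stable derived seed below 2**31."""
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31 - 1))


@dataclass
class FoldPlan:
    """Deterministic slide-to-fold assignment, stratified by label and
    optionally grouped by patient (a patient's slides never straddle a
    fold boundary)."""

    slide_ids: list[str]
    outer_assignments: dict[str, int]
    inner_assignments: dict[tuple[int, str], int]
    k_outer: int
    k_inner: int
    seed: int
    group_by_patient: bool

    def outer_split(self, fold: int) -> tuple[list[str], list[str]]:
        train = [s for s in self.slide_ids if self.outer_assignments[s] != fold]
        val = [s for s in self.slide_ids if self.outer_assignments[s] == fold]
        return train, val

    def inner_section(self, outer_fold: int) -> dict[str, int]:
        return {
            s: i for (f, s), i in self.inner_assignments.items() if f == outer_fold
        }


def make_fold_plan(
    slides: pd.DataFrame,
    k_outer: int = 3,
    k_inner: int = 5,
    seed: int = 0,
    group_by_patient: bool = True,
) -> FoldPlan:
    """Build a nested fold plan from a slide manifest.

    ``slides`` needs columns ``slide_id``, ``patient_id``, ``label``.
    The plan is keyed by sorted slide ids, so input row order is
    irrelevant given the seed.
    """
    if k_outer < 2 or k_inner < 2:
        raise ConfigError("k_outer and k_inner must both be >= 2")
    df = slides[["slide_id", "patient_id", "label"]].drop_duplicates("slide_id")
    df = df.sort_values("slide_id").reset_index(drop=True)
    counts = df["label"].value_counts()
    needed = k_outer * k_inner
    lacking = {int(c): int(counts.get(c, 0)) for c in (0, 1)
               if counts.get(c, 0) < needed}
    if lacking:
        raise InsufficientDataError(
            f"need >= {needed} slides per class for {k_outer}x{k_inner} nested CV; "
            f"per-class counts: {dict(counts.sort_index())}"
        )
    y = df["label"].to_numpy()
    groups = df["patient_id"].to_numpy()

    def _split(frame_idx: np.ndarray, k: int, split_seed: int) -> np.ndarray:
        sub_y = y[frame_idx]
        sub_g = groups[frame_idx]
        if group_by_patient and len(set(sub_g)) < len(sub_g):
            splitter = StratifiedGroupKFold(
                n_splits=k, shuffle=True, random_state=split_seed
            )
            it = splitter.split(frame_idx, sub_y, sub_g)
        else:
            splitter = StratifiedKFold(
                n_splits=k, shuffle=True, random_state=split_seed
            )
            it = splitter.split(frame_idx, sub_y)
        assignment = np.full(len(frame_idx), -1, dtype=int)
        for fold, (_, test_pos) in enumerate(it):
            assignment[test_pos] = fold
        return assignment

    all_idx = np.arange(len(df))
    outer = _split(all_idx, k_outer, _child_seed(seed, 1))
    outer_assignments = dict(zip(df["slide_id"], (int(v) for v in outer)))

    inner_assignments: dict[tuple[int, str], int] = {}
    for f in range(k_outer):
        train_idx = all_idx[outer != f]
        inner = _split(train_idx, k_inner, _child_seed(seed, 2, f))
        for pos, idx in enumerate(train_idx):
            inner_assignments[(f, df.at[idx, "slide_id"])] = int(inner[pos])

    return FoldPlan(
        slide_ids=list(df["slide_id"]),
        outer_assignments=outer_assignments,
        inner_assignments=inner_assignments,
        k_outer=k_outer,
        k_inner=k_inner,
        seed=seed,
        group_by_patient=group_by_patient,
    )


@dataclass
class NestedThresholdReport:
    """Per-inner-fold searches and the combined threshold set."""

    tile_searches: list[ThresholdSearchResult]
    slide_searches: list[ThresholdSearchResult]
    thresholds: ThresholdSet
    degenerate_tile_folds: int = 0
    degenerate_slide_folds: int = 0
    warnings: list[str] = field(default_factory=list)


def _slide_search_inputs(
    slides: Sequence[SlideResult],
) -> tuple[np.ndarray, np.ndarray]:
    """Slide uncertainties and correctness for the slide-level search.

    Fallback slides carry infinite uncertainty; the search needs finite
    values, so they are mapped to twice the largest finite uncertainty
    (plus one) — strictly above every real value, preserving order.
    Slide correctness uses the interim 0.5 cutoff because theta_pred is
    only determined afterwards.
    """
    u = np.array([s.slide_uncertainty for s in slides], dtype=float)
    finite = np.isfinite(u)
    if not finite.all():
        cap = (u[finite].max() * 2.0 + 1.0) if finite.any() else 1.0
        u = np.where(finite, u, cap)
    correct = np.array(
        [(s.slide_prediction >= 0.5) == bool(s.label) for s in slides], dtype=bool
    )
    return u, correct


def derive_thresholds_nested(
    outer_train_tiles: pd.DataFrame,
    inner_section: dict[str, int],
    predictor: PredictorContract,
    k_inner: int = 5,
) -> NestedThresholdReport:
    """Derive tile/slide uncertainty thresholds from an outer training
    set only, via inner cross-validation.

    ``outer_train_tiles`` needs columns ``tile_id``, ``slide_id``,
    ``label``; ``inner_section`` maps each of its slides to an inner
    fold.  For each inner fold the predictor is (re)fitted on the inner
    training tiles and ensembles are generated for the inner validation
    tiles; the tile search runs on tile uncertainties vs correctness,
    then slides are aggregated with that fold's tile threshold and the
    slide search runs on slide uncertainties vs slide correctness.
    """
    tile_searches: list[ThresholdSearchResult] = []
    slide_searches: list[ThresholdSearchResult] = []
    warnings: list[str] = []
    theta_tiles: list[float] = []
    theta_slides: list[float] = []
    n_deg_tile = n_deg_slide = 0

    slide_of = outer_train_tiles["slide_id"]
    for fold in range(k_inner):
        val_slides = {s for s, f in inner_section.items() if f == fold}
        train_mask = ~slide_of.isin(val_slides)
        train_tiles = outer_train_tiles[train_mask]
        val_tiles = outer_train_tiles[~train_mask]
        if val_tiles.empty:
            warnings.append(f"inner fold {fold}: empty validation set, skipped")
            continue
        predictor.fit(list(train_tiles["tile_id"]))
        ensembles = predictor.predict_ensemble(list(val_tiles["tile_id"]))
        results = estimate_all(ensembles)

        t_search = youden_uncertainty_search(
            [r.sigma_hat for r in results], [r.correct for r in results]
        )
        tile_searches.append(t_search)
        if t_search.is_degenerate:
            n_deg_tile += 1
            warnings.append(f"inner fold {fold} tile search: {t_search.degenerate}")
        else:
            theta_tiles.append(t_search.optimum)

        fold_theta_tile = t_search.optimum
        slides = aggregate_slides_uq(results, fold_theta_tile)
        u, correct = _slide_search_inputs(slides)
        s_search = youden_uncertainty_search(u, correct)
        slide_searches.append(s_search)
        if s_search.is_degenerate:
            n_deg_slide += 1
            warnings.append(f"inner fold {fold} slide search: {s_search.degenerate}")
        else:
            theta_slides.append(s_search.optimum)

    if theta_tiles:
        theta_tile = min(theta_tiles)
    else:
        theta_tile = HIGH_CONF_ALL
        warnings.append(
            "all inner folds degenerate at tile level; theta_tile = +inf sentinel"
        )
    if theta_slides:
        theta_slide = max(theta_slides)
    else:
        theta_slide = HIGH_CONF_ALL
        warnings.append(
            "all inner folds degenerate at slide level; theta_slide = +inf sentinel"
        )

    thresholds = ThresholdSet(
        theta_tile=theta_tile,
        theta_slide=theta_slide,
        inner_fold_theta_tile=[s.optimum for s in tile_searches],
        inner_fold_theta_slide=[s.optimum for s in slide_searches],
    )
    return NestedThresholdReport(
        tile_searches=tile_searches,
        slide_searches=slide_searches,
        thresholds=thresholds,
        degenerate_tile_folds=n_deg_tile,
        degenerate_slide_folds=n_deg_slide,
        warnings=warnings,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for a cross-validated uncertainty-thresholding
    experiment."""

    k_outer: int = 3
    k_inner: int = 5
    bootstrap_repeats: int = 2
    class_ratio: Optional[tuple[int, int]] = None  # subsample to this ratio
    use_uq: bool = True
    group_by_patient: bool = True
    seed: int = 0
    predictor_degradation: float = 0.0

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown experiment config fields: {sorted(unknown)}")
        if "class_ratio" in raw and raw["class_ratio"] is not None:
            raw = {**raw, "class_ratio": tuple(raw["class_ratio"])}
        return cls(**raw)


@dataclass
class FoldOutcome:
    repeat: int
    outer_fold: int
    thresholds: Optional[ThresholdSet]
    nested_report: Optional[NestedThresholdReport]
    slide_results: list[SlideResult]
    reports: list[EvalReport]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    folds: list[FoldOutcome]
    theta_pred_by_repeat: dict[int, float]

    def slides_table(self) -> pd.DataFrame:
        frames = []
        for fo in self.folds:
            f = slides_to_frame(fo.slide_results)
            f.insert(0, "outer_fold", fo.outer_fold)
            f.insert(0, "repeat", fo.repeat)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def reports_table(self) -> pd.DataFrame:
        rows = []
        for fo in self.folds:
            for r in fo.reports:
                rows.append({"repeat": fo.repeat, "outer_fold": fo.outer_fold,
                             **r.to_dict()})
        return pd.DataFrame(rows)

    def pooled_reports(self, level: str = "slide") -> list[EvalReport]:
        """Cohort reports over all outer-validation slides pooled across
        repeats and folds (theta_pred of each repeat applies to its own
        slides only when computing correctness; pooling uses the mean)."""
        slides = [s for fo in self.folds for s in fo.slide_results]
        theta = float(np.mean(list(self.theta_pred_by_repeat.values())))
        if self.config.use_uq:
            return cohort_report(slides, theta, level=level)  # type: ignore[arg-type]
        preds = np.array([s.slide_prediction for s in slides])
        labels = np.array([s.label for s in slides])
        return [single_cohort_report(level, "all", preds, labels, theta)]  # type: ignore[arg-type]


def _ratio_subsample(
    manifest: pd.DataFrame, ratio: tuple[int, int], seed: int
) -> pd.DataFrame:
    """Deterministically subsample ordinary slides to a class0:class1
    ratio; intermediate slides (random labels) are kept as-is."""
    a, b = ratio
    if "is_intermediate" in manifest.columns:
        is_inter = manifest["is_intermediate"].astype(bool)
    else:
        is_inter = pd.Series(False, index=manifest.index)
    ordinary = manifest[~is_inter]
    inter = manifest[is_inter]
    n0 = int((ordinary["label"] == 0).sum())
    n1 = int((ordinary["label"] == 1).sum())
    scale = min(n0 / a, n1 / b)
    want0, want1 = int(math.floor(scale * a)), int(math.floor(scale * b))
    if want0 < 1 or want1 < 1:
        raise InsufficientDataError(
            f"ratio {a}:{b} exhausts a class (available {n0}:{n1})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4A710]))
    picked = []
    for label, want in ((0, want0), (1, want1)):
        ids = np.sort(ordinary.loc[ordinary["label"] == label, "slide_id"].to_numpy())
        picked.append(rng.choice(ids, size=want, replace=False))
    keep = set(np.concatenate(picked)) | set(inter["slide_id"])
    return manifest[manifest["slide_id"].isin(keep)].reset_index(drop=True)


def run_crossval_experiment(
    dataset,
    config: ExperimentConfig,
    predictor_factory: Optional[Callable[[int], PredictorContract]] = None,
) -> ExperimentResult:
    """Run the full bootstrapped outer-CV experiment on a dataset.

    ``dataset`` must expose ``tiles`` (tile table with tile_id,
    slide_id, patient_id, label) and ``manifest`` (slide table); the
    bundled synthetic datasets do.  ``predictor_factory(seed)`` builds a
    fresh predictor per repeat; by default an oracle predictor backed by
    the dataset's latent state.

    Per repeat: a fresh fold plan; per outer fold: thresholds derived by
    nested inner CV on the outer training set (UQ mode only), ensembles
    predicted for outer-validation tiles, slides aggregated and flagged;
    after all folds of the repeat, theta_pred is found by Youden on the
    pooled outer-validation slide predictions and cohort reports are
    emitted per fold.
    """
    from .synthetic import oracle_predictor  # local: avoid cycle

    manifest = dataset.manifest
    if config.class_ratio is not None:
        manifest = _ratio_subsample(manifest, config.class_ratio, config.seed)
    tiles = dataset.tiles[dataset.tiles["slide_id"].isin(manifest["slide_id"])]

    if predictor_factory is None:
        def predictor_factory(seed: int) -> PredictorContract:
            return oracle_predictor(
                dataset, seed=seed, degradation=config.predictor_degradation
            )

    folds: list[FoldOutcome] = []
    theta_pred_by_repeat: dict[int, float] = {}
    for repeat in range(config.bootstrap_repeats):
        plan = make_fold_plan(
            manifest,
            k_outer=config.k_outer,
            k_inner=config.k_inner,
            seed=_child_seed(config.seed, 10, repeat),
            group_by_patient=config.group_by_patient,
        )
        predictor = predictor_factory(_child_seed(config.seed, 11, repeat))
        repeat_outcomes: list[FoldOutcome] = []
        for f in range(config.k_outer):
            train_slides, val_slides = plan.outer_split(f)
            train_tiles = tiles[tiles["slide_id"].isin(train_slides)]
            val_tiles = tiles[tiles["slide_id"].isin(val_slides)]

            thresholds = None
            nested_report = None
            if config.use_uq:
                nested_report = derive_thresholds_nested(
                    train_tiles, plan.inner_section(f), predictor,
                    k_inner=config.k_inner,
                )
                thresholds = nested_report.thresholds

            predictor.fit(list(train_tiles["tile_id"]))
            ensembles = predictor.predict_ensemble(list(val_tiles["tile_id"]))
            results = estimate_all(ensembles)
            if config.use_uq:
                assert thresholds is not None
                slides = aggregate_slides_uq(results, thresholds.theta_tile)
                slides = assign_slide_confidence(slides, thresholds.theta_slide)
            else:
                slides = aggregate_slides_nonuq(results)
            repeat_outcomes.append(
                FoldOutcome(
                    repeat=repeat, outer_fold=f, thresholds=thresholds,
                    nested_report=nested_report, slide_results=slides, reports=[],
                )
            )

        pooled = [s for fo in repeat_outcomes for s in fo.slide_results]
        p_search = prediction_threshold_search(
            [s.slide_prediction for s in pooled], [s.label for s in pooled]
        )
        theta_pred = p_search.optimum
        theta_pred_by_repeat[repeat] = theta_pred
        for fo in repeat_outcomes:
            if fo.thresholds is not None:
                fo.thresholds.theta_pred = theta_pred
            if config.use_uq:
                fo.reports = cohort_report(fo.slide_results, theta_pred)
            else:
                preds = np.array([s.slide_prediction for s in fo.slide_results])
                labels = np.array([s.label for s in fo.slide_results])
                fo.reports = [
                    single_cohort_report("slide", "all", preds, labels, theta_pred)
                ]
        folds.extend(repeat_outcomes)

    return ExperimentResult(
        config=config, folds=folds, theta_pred_by_repeat=theta_pred_by_repeat
    )
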