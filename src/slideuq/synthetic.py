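"""Synthetic tile-ensemble datasets with the statistical structure the
uncertainty-thresholding method assumes.

The generator emulates, on the probability scale, the qualitative
behaviour of Monte Carlo dropout ensembles from a well-trained binary
tile classifier:

* *clear* tiles concentrate near their class pole (mean at
  ``pole ± clear_center_offset``) with a small pass-to-pass spread, so
  they are almost always correctly predicted and carry low uncertainty;
* *ambiguous* tiles sit near the decision boundary (per-tile centre
  jittered around 0.5) with a large pass-to-pass spread, so they are
  mispredicted roughly half the time and carry high uncertainty;
* *intermediate* slides consist purely of ambiguous tiles and carry a
  uniformly random label — a decision-boundary stress test for the
  thresholding machinery, mimicking slides synthesised by interpolating
  between the two classes in a generative model's latent space.

Pass values are drawn as clipped Gaussians on [0, 1]; clipping slightly
shrinks moments near the poles, which tests account for with tolerance
bands.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ensembles import TileEnsemble
from .errors import ConfigError, ContractError

_POLE = {0: 0.0, 1: 1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic ensemble dataset.

    Defaults are desk-scale study conditions: 200 slides per class of
    200 tiles each with 30 forward passes, 10% ambiguous tiles per
    ordinary slide, and 10% pure-ambiguous randomly-labelled
    intermediate slides so that the abstention machinery always has
    genuinely uncertain slides to reject (matching the ~80-95%
    high-confidence rates typical of validation cohorts).
    """

    n_slides_per_class: int = 200
    tiles_per_slide: int = 200
    passes: int = 30
    clear_center_offset: float = 0.15
    clear_pass_sd: float = 0.05
    ambiguous_pass_sd: float = 0.25
    ambiguous_center_sd: float = 0.08
    ambiguous_tile_fraction: float = 0.10
    intermediate_slide_fraction: float = 0.10
    class_ratio: Tuple[int, int] = (1, 1)
    multi_slide_patient_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_slides_per_class < 1:
            raise ConfigError("n_slides_per_class must be >= 1")
        if self.tiles_per_slide < 1:
            raise ConfigError("tiles_per_slide must be >= 1")
        if self.passes < 2:
            raise ConfigError("passes must be >= 2")
        if not (0.0 < self.clear_center_offset <= 0.5):
            raise ConfigError("clear_center_offset must lie in (0, 0.5]")
        if self.clear_pass_sd < 0.0:
            raise ConfigError("clear_pass_sd must be >= 0")
        if self.ambiguous_pass_sd <= self.clear_pass_sd:
            raise ConfigError("ambiguous_pass_sd must exceed clear_pass_sd")
        for name in (
            "ambiguous_tile_fraction",
            "intermediate_slide_fraction",
            "multi_slide_patient_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        a, b = self.class_ratio
        if a < 1 or b < 1:
            raise ConfigError("class_ratio parts must be positive integers")

    def slides_per_class(self) -> Tuple[int, int]:
        """Ordinary slide counts per class under the configured ratio.

        The majority class keeps ``n_slides_per_class`` slides; the
        minority is scaled by the ratio and rounded half-up.
        """
        a, b = self.class_ratio
        m = max(a, b)
        n0 = int(round(self.n_slides_per_class * a / m))
        n1 = int(round(self.n_slides_per_class * b / m))
        return n0, n1


@dataclass
class SyntheticDataset:
    """Latent tile table + slide manifest + (lazily materialised)
    ensembles.

    ``tiles`` has one row per tile with its latent generative state
    (``is_ambiguous``, ``center``, ``pass_sd``); ``manifest`` has one
    row per slide (``slide_id``, ``patient_id``, ``label``,
    ``is_intermediate``).
    """

    tiles: pd.DataFrame
    manifest: pd.DataFrame
    config: SimulationConfig
    seed: int

    @cached_property
    def ensembles(self) -> list[TileEnsemble]:
        """Materialise one ensemble per tile, deterministic in the seed."""
        return _draw_ensembles(self.tiles, self.config.passes, np.random.default_rng(
            np.random.SeedSequence([self.seed, 0xE45E])))

    def slide_labels(self) -> pd.Series:
        return self.manifest.set_index("slide_id")["label"]


def _draw_ensembles(
    tiles: pd.DataFrame, passes: int, rng: np.random.Generator
) -> list[TileEnsemble]:
    centers = tiles["center"].to_numpy()
    sds = tiles["pass_sd"].to_numpy()
    dev = rng.standard_normal((len(tiles), passes))
    values = np.clip(centers[:, None] + sds[:, None] * dev, 0.0, 1.0)
    return [
        TileEnsemble(
            tile_id=row.tile_id,
            slide_id=row.slide_id,
            patient_id=row.patient_id,
            label=int(row.label),
            pass_values=tuple(values[i]),
        )
        for i, row in enumerate(tiles.itertuples(index=False))
    ]


def _make_slide_block(
    slide_id: str,
    patient_id: str,
    label: int,
    n_tiles: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    pure_ambiguous: bool,
) -> pd.DataFrame:
    if pure_ambiguous:
        ambiguous = np.ones(n_tiles, dtype=bool)
    else:
        ambiguous = rng.random(n_tiles) < cfg.ambiguous_tile_fraction
    centers = np.where(
        ambiguous,
        np.clip(0.5 + cfg.ambiguous_center_sd * rng.standard_normal(n_tiles), 0.0, 1.0),
        np.clip(_POLE[label] + (1 - 2 * label) * cfg.clear_center_offset, 0.0, 1.0),
    )
    sds = np.where(ambiguous, cfg.ambiguous_pass_sd, cfg.clear_pass_sd)
    return pd.DataFrame(
        {
            "tile_id": [f"{slide_id}_t{i:04d}" for i in range(n_tiles)],
            "slide_id": slide_id,
            "patient_id": patient_id,
            "label": label,
            "is_ambiguous": ambiguous,
            "center": centers,
            "pass_sd": sds,
        }
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset under ``config``.

    Ordinary slides are emitted per class (counts set by the class
    ratio), then intermediate slides are appended so that they make up
    ``intermediate_slide_fraction`` of all slides (count rounded to
    nearest).  One patient per slide unless
    ``multi_slide_patient_fraction`` > 0, in which case that fraction of
    ordinary slides is reassigned to share the patient of another slide
    with the same label.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51DE]))
    n0, n1 = config.slides_per_class()

    blocks: list[pd.DataFrame] = []
    manifest_rows: list[dict] = []
    for label, count in ((0, n0), (1, n1)):
        for k in range(count):
            slide_id = f"S{label}_{k:04d}"
            patient_id = f"P_{slide_id}"
            blocks.append(
                _make_slide_block(
                    slide_id, patient_id, label, config.tiles_per_slide,
                    config, rng, pure_ambiguous=False,
                )
            )
            manifest_rows.append(
                {"slide_id": slide_id, "patient_id": patient_id,
                 "label": label, "is_intermediate": False}
            )

    # Optionally merge a fraction of slides into multi-slide patients
    # (same-label pairs, so a slide still maps to one label per patient).
    if config.multi_slide_patient_fraction > 0:
        manifest = pd.DataFrame(manifest_rows)
        n_merge = int(round(config.multi_slide_patient_fraction * len(manifest)))
        for label in (0, 1):
            idx = manifest.index[manifest["label"] == label].to_numpy()
            take = idx[: 2 * (min(n_merge // 2, len(idx) // 2))]
            for i in range(0, len(take), 2):
                donor, recipient = take[i], take[i + 1]
                pid = manifest.at[donor, "patient_id"]
                manifest.at[recipient, "patient_id"] = pid
        pid_map = manifest.set_index("slide_id")["patient_id"]
        for b in blocks:
            b["patient_id"] = pid_map[b["slide_id"].iloc[0]]
        manifest_rows = manifest.to_dict("records")

    n_ordinary = len(manifest_rows)
    f = config.intermediate_slide_fraction
    n_intermediate = int(round(f / (1.0 - f) * n_ordinary)) if f < 1.0 else 0
    for k in range(n_intermediate):
        label = int(rng.integers(0, 2))
        slide_id = f"SI_{k:04d}"
        patient_id = f"P_{slide_id}"
        blocks.append(
            _make_slide_block(
                slide_id, patient_id, label, config.tiles_per_slide,
                config, rng, pure_ambiguous=True,
            )
        )
        manifest_rows.append(
            {"slide_id": slide_id, "patient_id": patient_id,
             "label": label, "is_intermediate": True}
        )

    tiles = pd.concat(blocks, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows)
    return SyntheticDataset(tiles=tiles, manifest=manifest, config=config,
                            seed=config.seed)


def add_intermediate_slides(
    dataset: SyntheticDataset,
    fraction: Optional[float] = None,
    count: Optional[int] = None,
    tiles_per_slide: int = 1000,
    seed: Optional[int] = None,
) -> SyntheticDataset:
    """Append pure-ambiguous, randomly-labelled slides to a dataset.

    ``fraction`` is interpreted against the final total (0.5 doubles the
    dataset); alternatively give an explicit ``count``.  Each appended
    slide has ``tiles_per_slide`` ambiguous tiles (default 1000, the
    scale at which decision-boundary slides are typically synthesised).
    """
    if (fraction is None) == (count is None):
        raise ConfigError("give exactly one of fraction or count")
    n_existing = len(dataset.manifest)
    if fraction is not None:
        if not (0.0 <= fraction < 1.0):
            raise ConfigError("fraction must lie in [0, 1)")
        count = int(round(fraction / (1.0 - fraction) * n_existing))
    assert count is not None
    if count < 0:
        raise ConfigError("count must be >= 0")
    if count == 0:
        return dataset
    rng = np.random.default_rng(
        np.random.SeedSequence([seed if seed is not None else dataset.seed, 0xADD1])
    )
    existing_ids = set(dataset.manifest["slide_id"])
    blocks, manifest_rows = [], []
    k0 = 0
    for _ in range(count):
        while f"SX_{k0:04d}" in existing_ids:
            k0 += 1
        slide_id = f"SX_{k0:04d}"
        k0 += 1
        label = int(rng.integers(0, 2))
        patient_id = f"P_{slide_id}"
        blocks.append(
            _make_slide_block(
                slide_id, patient_id, label, tiles_per_slide,
                dataset.config, rng, pure_ambiguous=True,
            )
        )
        manifest_rows.append(
            {"slide_id": slide_id, "patient_id": patient_id,
             "label": label, "is_intermediate": True}
        )
    tiles = pd.concat([dataset.tiles] + blocks, ignore_index=True)
    manifest = pd.concat(
        [dataset.manifest, pd.DataFrame(manifest_rows)], ignore_index=True
    )
    return SyntheticDataset(
        tiles=tiles, manifest=manifest, config=dataset.config, seed=dataset.seed
    )


class OraclePredictor:
    """Predictor contract backed by the generator's latent tile state.

    ``fit`` is a no-op that records the training-set size;
    ``predict_ensemble`` regenerates each requested tile's ensemble from
    its latent centre/spread and the contract seed.  Per-tile deviations
    are drawn once, in the dataset's canonical tile order, so ensembles
    are deterministic regardless of how tiles are batched into folds.

    With ``degradation > 0`` the pass spread is widened as the training
    set shrinks (multiplier ``(reference_train_size / n_train) **
    degradation``), giving nested cross-validation authentic per-fold
    variation in uncertainty scale.
    """

    def __init__(
        self,
        dataset: SyntheticDataset,
        seed: int = 0,
        degradation: float = 0.0,
        reference_train_size: int = 10_000,
    ):
        self._tiles = dataset.tiles.set_index("tile_id", drop=False)
        if not {"center", "pass_sd"} <= set(self._tiles.columns):
            raise ContractError("tiles lack latent-type metadata (center/pass_sd)")
        self.seed = seed
        self.degradation = degradation
        self.reference_train_size = reference_train_size
        self.passes = dataset.config.passes
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0AC1E]))
        self._dev = rng.standard_normal((len(self._tiles), self.passes))
        self._row_of = {t: i for i, t in enumerate(self._tiles["tile_id"])}
        self.n_train_tiles: Optional[int] = None

    def fit(self, train_tile_ids: Sequence[str]) -> "OraclePredictor":
        self.n_train_tiles = len(train_tile_ids)
        return self

    def _sd_multiplier(self) -> float:
        if self.degradation == 0.0:
            return 1.0
        if self.n_train_tiles is None or self.n_train_tiles == 0:
            raise ContractError("predictor must be fit before predicting")
        return (self.reference_train_size / self.n_train_tiles) ** self.degradation

    def predict_ensemble(self, tile_ids: Sequence[str]) -> list[TileEnsemble]:
        try:
            rows = [self._row_of[t] for t in tile_ids]
        except KeyError as exc:
            raise ContractError(f"unknown tile {exc.args[0]!r}") from exc
        sub = self._tiles.iloc[rows]
        m = self._sd_multiplier()
        centers = sub["center"].to_numpy()
        sds = sub["pass_sd"].to_numpy() * m
        values = np.clip(centers[:, None] + sds[:, None] * self._dev[rows], 0.0, 1.0)
        return [
            TileEnsemble(
                tile_id=row.tile_id,
                slide_id=row.slide_id,
                patient_id=row.patient_id,
                label=int(row.label),
                pass_values=tuple(values[i]),
            )
            for i, row in enumerate(sub.itertuples(index=False))
        ]


def oracle_predictor(
    dataset: SyntheticDataset,
    seed: int = 0,
    degradation: float = 0.0,
    reference_train_size: int = 10_000,
) -> OraclePredictor:
    """Convenience constructor for :class:`OraclePredictor`."""
    return OraclePredictor(
        dataset, seed=seed, degradation=degradation,
        reference_train_size=reference_train_size,
    )
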