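"""Forward-pass prediction ensembles and tile-level uncertainty.

A *tile ensemble* is the set of ``J`` predictions obtained for one image
tile by running a dropout-enabled classifier ``J`` times with dropout
active at inference (Monte Carlo dropout).  The mean of the ensemble is
the tile's prediction ``mu_hat`` and the *population* standard deviation
(denominator ``J``, not ``J - 1``) is the tile's uncertainty
``sigma_hat``.  The population form is deliberate: the ensemble is treated
as an exhaustive sample of the dropout posterior draw, and most standard
std routines default to the sample estimator, so callers porting code
should take note.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Tuple

import numpy as np

from .errors import DomainError, EmptyInputError, IntegrityError, InvalidEnsembleError

DEFAULT_PASSES = 30

Confidence = Literal["high", "low", "unset"]


@dataclass(frozen=True)
class TileEnsemble:
    """One tile's dropout forward-pass outputs plus identifiers.

    ``label`` follows the convention 0 = adenocarcinoma-like,
    1 = squamous-like.  ``pass_values`` holds the ``J >= 2`` per-pass
    predictions, each in [0, 1].  ``grid_xy`` are optional 0-based
    (column, row) tile coordinates used only for heatmap export.
    """

    tile_id: str
    slide_id: str
    patient_id: str
    label: int
    pass_values: Tuple[float, ...]
    grid_xy: Optional[Tuple[int, int]] = None

    def validate(self) -> None:
        if len(self.pass_values) < 2:
            raise InvalidEnsembleError(
                f"tile {self.tile_id!r}: ensemble needs >= 2 passes, "
                f"got {len(self.pass_values)}"
            )
        values = np.asarray(self.pass_values, dtype=float)
        if not np.all(np.isfinite(values)) or values.min() < 0.0 or values.max() > 1.0:
            raise DomainError(
                f"tile {self.tile_id!r}: pass values must lie in [0, 1]"
            )
        if self.label not in (0, 1):
            raise DomainError(f"tile {self.tile_id!r}: label must be 0 or 1")


@dataclass
class TileResult:
    """Per-tile estimate: prediction ``mu_hat``, uncertainty ``sigma_hat``,
    correctness at the 0.5 cutoff, and a confidence flag (set later by
    thresholding)."""

    tile_id: str
    slide_id: str
    patient_id: str
    label: int
    mu_hat: float
    sigma_hat: float
    predicted_class: int
    correct: bool
    confidence: Confidence = "unset"
    grid_xy: Optional[Tuple[int, int]] = None

    def with_confidence(self, confidence: Confidence) -> "TileResult":
        return replace(self, confidence=confidence)


def _classify(mu_hat: float) -> int:
    # Ties at exactly 0.5 go to class 1 (documented convention; the
    # aggregation cutoff is symmetric so the choice only matters for
    # exactly-tied means).
    return 1 if mu_hat >= 0.5 else 0


def estimate_tile(ensemble: TileEnsemble) -> TileResult:
    """Estimate one tile's prediction and uncertainty from its ensemble.

    ``mu_hat`` is the arithmetic mean of the pass values; ``sigma_hat``
    is the population standard deviation (denominator ``J``).
    """
    ensemble.validate()
    values = np.asarray(ensemble.pass_values, dtype=float)
    mu = float(values.mean())
    # constant ensembles are exactly zero-spread (no rounding residue)
    sigma = 0.0 if values.min() == values.max() else float(values.std(ddof=0))
    pred = _classify(mu)
    return TileResult(
        tile_id=ensemble.tile_id,
        slide_id=ensemble.slide_id,
        patient_id=ensemble.patient_id,
        label=ensemble.label,
        mu_hat=mu,
        sigma_hat=sigma,
        predicted_class=pred,
        correct=(pred == ensemble.label),
        grid_xy=ensemble.grid_xy,
    )


def estimate_all(ensembles: Iterable[TileEnsemble]) -> list[TileResult]:
    """Estimate every tile in a collection, preserving input order.

    Vectorised when all ensembles share the same pass count ``J`` (the
    usual case); falls back to per-tile estimation otherwise.
    """
    ens = list(ensembles)
    if not ens:
        raise EmptyInputError("estimate_all received an empty collection")
    ids = [e.tile_id for e in ens]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise IntegrityError(f"duplicate tile_id {dup!r}")
    lengths = {len(e.pass_values) for e in ens}
    if len(lengths) != 1:
        return [estimate_tile(e) for e in ens]
    j = lengths.pop()
    if j < 2:
        raise InvalidEnsembleError(f"ensembles need >= 2 passes, got {j}")
    values = np.asarray([e.pass_values for e in ens], dtype=float)
    if not np.all(np.isfinite(values)) or values.min() < 0.0 or values.max() > 1.0:
        bad = np.where(~((values >= 0.0) & (values <= 1.0)) | ~np.isfinite(values))[0]
        raise DomainError(
            f"pass values outside [0, 1] for tile(s) "
            f"{[ens[i].tile_id for i in np.unique(bad)[:5]]}"
        )
    mu = values.mean(axis=1)
    sigma = values.std(axis=1, ddof=0)
    sigma[values.min(axis=1) == values.max(axis=1)] = 0.0
    preds = (mu >= 0.5).astype(int)
    return [
        TileResult(
            tile_id=e.tile_id,
            slide_id=e.slide_id,
            patient_id=e.patient_id,
            label=e.label,
            mu_hat=float(mu[i]),
            sigma_hat=float(sigma[i]),
            predicted_class=int(preds[i]),
            correct=bool(preds[i] == e.label),
            grid_xy=e.grid_xy,
        )
        for i, e in enumerate(ens)
    ]
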