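"""Schematic slide heatmaps: prediction, uncertainty, and
high-confidence-only panels.

Each tile with 0-based (column, row) grid coordinates is rendered as a
square pixel block.  Predictions map through a purple-to-green
colormap (0 = adenocarcinoma-like = purple, 1 = squamous-like =
green), uncertainties through a sequential map on [0, 0.5] (the
maximum possible ensemble standard deviation), and the third panel
repeats the prediction map with low-confidence tiles masked to the
background colour.  Grid gaps render as background.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .ensembles import TileResult
from .errors import EmptyInputError, StateError

PREDICTION_CMAP = "PRGn"  # low -> purple, high -> green
UNCERTAINTY_CMAP = "inferno"
BACKGROUND_RGB = (235, 235, 235)
MAX_SIGMA = 0.5


def _colormap_rgb(name: str, values: np.ndarray) -> np.ndarray:
    cmap = colormaps[name]
    rgba = cmap(np.clip(values, 0.0, 1.0))
    return (rgba[:, :3] * 255).round().astype(np.uint8)


def prediction_rgb(values: np.ndarray) -> np.ndarray:
    """RGB for predictions in [0,1]: 0 maps to purple, 1 to green."""
    return _colormap_rgb(PREDICTION_CMAP, values)


def uncertainty_rgb(values: np.ndarray) -> np.ndarray:
    """RGB for uncertainties, normalised by the 0.5 upper bound."""
    return _colormap_rgb(UNCERTAINTY_CMAP, values / MAX_SIGMA)


def export_heatmap(
    tiles: Sequence[TileResult],
    theta_tile: float,
    out_prefix: Union[str, Path],
    scale: int = 16,
) -> dict[str, Path]:
    """Write the three heatmap panels for one slide.

    Returns the written paths keyed ``prediction``, ``uncertainty``,
    ``high_confidence``.  Every tile must carry ``grid_xy``.
    """
    if not tiles:
        raise EmptyInputError("export_heatmap received no tiles")
    for t in tiles:
        if t.grid_xy is None:
            raise StateError(f"tile {t.tile_id!r} lacks grid_xy coordinates")
    cols = np.array([t.grid_xy[0] for t in tiles])  # type: ignore[index]
    rows = np.array([t.grid_xy[1] for t in tiles])  # type: ignore[index]
    mu = np.array([t.mu_hat for t in tiles])
    sigma = np.array([t.sigma_hat for t in tiles])
    high = sigma < theta_tile

    h, w = int(rows.max()) + 1, int(cols.max()) + 1
    panels = {
        "prediction": np.full((h, w, 3), BACKGROUND_RGB, dtype=np.uint8),
        "uncertainty": np.full((h, w, 3), BACKGROUND_RGB, dtype=np.uint8),
        "high_confidence": np.full((h, w, 3), BACKGROUND_RGB, dtype=np.uint8),
    }
    pred_rgb = prediction_rgb(mu)
    unc_rgb = uncertainty_rgb(sigma)
    panels["prediction"][rows, cols] = pred_rgb
    panels["uncertainty"][rows, cols] = unc_rgb
    panels["high_confidence"][rows[high], cols[high]] = pred_rgb[high]

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, arr in panels.items():
        big = np.kron(arr, np.ones((scale, scale, 1), dtype=np.uint8))
        path = out_prefix.with_name(f"{out_prefix.name}_{name}.png")
        Image.fromarray(big).save(path)
        paths[name] = path
    return paths
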