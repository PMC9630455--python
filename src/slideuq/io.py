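"""File formats: ensemble tables, result tables, threshold sets,
configs, and provenance records.

Tabular files are comma-separated UTF-8 with a header row.  Two
ensemble dialects exist: *long* (one row per tile per forward pass,
columns ``tile_id, slide_id, patient_id, label, pass_index, value``)
and *wide* (one row per tile, pass columns ``pass_0 ... pass_{J-1}``).
Floats serialise with 17 significant digits so round-trips and re-runs
are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import PatientResult, SlideResult, patients_to_frame, slides_to_frame
from .ensembles import TileEnsemble, TileResult
from .errors import DomainError, FormatError, SchemaError
from .thresholding import ThresholdSet

FLOAT_FORMAT = "%.17g"

LONG_COLUMNS = ["tile_id", "slide_id", "patient_id", "label", "pass_index", "value"]
ID_COLUMNS = ["tile_id", "slide_id", "patient_id", "label"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: object) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_values(values: np.ndarray, rows: np.ndarray, path: object) -> None:
    bad = ~((values >= 0.0) & (values <= 1.0)) | ~np.isfinite(values)
    if bad.any():
        where = rows[bad][:5].tolist()
        raise DomainError(
            f"{path}: pass values outside [0, 1] at data row(s) {where}"
        )


def read_ensembles(
    path: Union[str, Path], format: Literal["long", "wide"] = "long"
) -> list[TileEnsemble]:
    """Read tile ensembles from a CSV file in either dialect.

    Row order is irrelevant; pass indices must be 0-based and
    contiguous within each tile.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if format == "long":
        _require_columns(df, LONG_COLUMNS, path)
        _check_values(df["value"].to_numpy(float), df.index.to_numpy(), path)
        ensembles = []
        for tile_id, grp in df.groupby("tile_id", sort=True):
            grp = grp.sort_values("pass_index")
            idx = grp["pass_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise FormatError(
                    f"{path}: tile {tile_id!r} pass indices not contiguous from 0"
                )
            first = grp.iloc[0]
            ensembles.append(
                TileEnsemble(
                    tile_id=str(tile_id),
                    slide_id=str(first["slide_id"]),
                    patient_id=str(first["patient_id"]),
                    label=int(first["label"]),
                    pass_values=tuple(grp["value"].astype(float)),
                )
            )
        return ensembles
    if format == "wide":
        _require_columns(df, ID_COLUMNS, path)
        pass_cols = sorted(
            (c for c in df.columns if c.startswith("pass_")),
            key=lambda c: int(c.split("_", 1)[1]),
        )
        if not pass_cols:
            raise SchemaError(f"{path}: no pass_* columns found")
        expected = [f"pass_{i}" for i in range(len(pass_cols))]
        if pass_cols != expected:
            raise FormatError(f"{path}: pass columns not contiguous from pass_0")
        values = df[pass_cols].to_numpy(float)
        _check_values(values.ravel(), np.repeat(df.index.to_numpy(), len(pass_cols)),
                      path)
        has_grid = {"grid_x", "grid_y"} <= set(df.columns)
        return [
            TileEnsemble(
                tile_id=str(row["tile_id"]),
                slide_id=str(row["slide_id"]),
                patient_id=str(row["patient_id"]),
                label=int(row["label"]),
                pass_values=tuple(values[i]),
                grid_xy=(int(row["grid_x"]), int(row["grid_y"])) if has_grid else None,
            )
            for i, (_, row) in enumerate(df.iterrows())
        ]
    raise FormatError(f"unknown ensemble format {format!r}")


def write_ensembles(
    path: Union[str, Path],
    ensembles: Iterable[TileEnsemble],
    format: Literal["long", "wide"] = "long",
) -> None:
    path = Path(path)
    ens = list(ensembles)
    if format == "long":
        rows = {c: [] for c in LONG_COLUMNS}
        for e in ens:
            for j, v in enumerate(e.pass_values):
                rows["tile_id"].append(e.tile_id)
                rows["slide_id"].append(e.slide_id)
                rows["patient_id"].append(e.patient_id)
                rows["label"].append(e.label)
                rows["pass_index"].append(j)
                rows["value"].append(v)
        pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)
        return
    if format == "wide":
        n_passes = {len(e.pass_values) for e in ens}
        if len(n_passes) > 1:
            raise FormatError("wide format requires a uniform pass count")
        j = n_passes.pop() if n_passes else 0
        data = {
            "tile_id": [e.tile_id for e in ens],
            "slide_id": [e.slide_id for e in ens],
            "patient_id": [e.patient_id for e in ens],
            "label": [e.label for e in ens],
        }
        if all(e.grid_xy is not None for e in ens) and ens:
            data["grid_x"] = [e.grid_xy[0] for e in ens]  # type: ignore[index]
            data["grid_y"] = [e.grid_xy[1] for e in ens]  # type: ignore[index]
        for k in range(j):
            data[f"pass_{k}"] = [e.pass_values[k] for e in ens]
        pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)
        return
    raise FormatError(f"unknown ensemble format {format!r}")


def write_tile_results(path: Union[str, Path], results: Sequence[TileResult]) -> None:
    df = pd.DataFrame(
        {
            "tile_id": [r.tile_id for r in results],
            "slide_id": [r.slide_id for r in results],
            "patient_id": [r.patient_id for r in results],
            "label": [r.label for r in results],
            "mu_hat": [r.mu_hat for r in results],
            "sigma_hat": [r.sigma_hat for r in results],
            "predicted_class": [r.predicted_class for r in results],
            "correct": [r.correct for r in results],
            "confidence": [r.confidence for r in results],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_tile_results(path: Union[str, Path]) -> list[TileResult]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df,
        ["tile_id", "slide_id", "patient_id", "label", "mu_hat", "sigma_hat",
         "predicted_class", "correct", "confidence"],
        path,
    )
    return [
        TileResult(
            tile_id=str(r["tile_id"]),
            slide_id=str(r["slide_id"]),
            patient_id=str(r["patient_id"]),
            label=int(r["label"]),
            mu_hat=float(r["mu_hat"]),
            sigma_hat=float(r["sigma_hat"]),
            predicted_class=int(r["predicted_class"]),
            correct=bool(r["correct"]),
            confidence=str(r["confidence"]),  # type: ignore[arg-type]
        )
        for _, r in df.iterrows()
    ]


def write_slide_results(path: Union[str, Path], slides: Sequence[SlideResult]) -> None:
    slides_to_frame(slides).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_slide_results(path: Union[str, Path]) -> list[SlideResult]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df,
        ["slide_id", "patient_id", "label", "prediction", "uncertainty",
         "confidence", "n_tiles", "n_high_conf_tiles", "fallback_used"],
        path,
    )
    out = []
    for _, r in df.iterrows():
        u = float(r["uncertainty"])
        out.append(
            SlideResult(
                slide_id=str(r["slide_id"]),
                patient_id=str(r["patient_id"]),
                label=int(r["label"]),
                slide_uncertainty=None if np.isnan(u) else u,
                slide_prediction=float(r["prediction"]),
                n_tiles=int(r["n_tiles"]),
                n_high_conf_tiles=int(r["n_high_conf_tiles"]),
                confidence=str(r["confidence"]),  # type: ignore[arg-type]
                fallback_used=bool(r["fallback_used"]),
            )
        )
    return out


def write_patient_results(
    path: Union[str, Path], patients: Sequence[PatientResult]
) -> None:
    patients_to_frame(patients).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_thresholds(path: Union[str, Path], thresholds: ThresholdSet) -> None:
    Path(path).write_text(thresholds.to_json() + "\n", encoding="utf-8")


def read_thresholds(path: Union[str, Path]) -> ThresholdSet:
    return ThresholdSet.from_json(Path(path).read_text(encoding="utf-8"))


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON experiment/simulation config."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_provenance(
    out_dir: Union[str, Path],
    command: str,
    seed: Optional[int],
    config: dict,
) -> Path:
    """Write the run's provenance record (config echo, seed, version).

    Deliberately excludes wall-clock information so identical runs
    produce identical artifacts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "seed": seed,
        "config": config,
        "slideuq_version": __version__,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, sort_keys=True, indent=2) + "\n",
                    encoding="utf-8")
    return path
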