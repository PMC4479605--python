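"""Movie and table I/O: multi-page TIFF (T, C, Y, X) with a JSON sidecar for
timestamps, dose, calibration and seed; CSV tables for everything else."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import Movie


def write_movie(path: str | Path, movie: Movie, seed: int | None = None) -> Path:
    """Write a movie as multi-page TIFF plus a ``<stem>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.pixels.astype(np.float32), metadata={"axes": "TCYX"})
    sidecar = {
        "times_min": movie.times_min.tolist(),
        "pixel_size_um": movie.pixel_size_um,
        "dose_gy": movie.dose_gy,
        "seed": seed,
        "axes": "TCYX",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_movie(path: str | Path) -> Movie:
    """Read a movie written by :func:`write_movie` (TIFF + JSON sidecar)."""
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 3:  # single channel stored as (T, Y, X)
        pixels = pixels[:, None, :, :]
    meta = json.loads(path.with_suffix(".json").read_text())
    return Movie(
        pixels=np.asarray(pixels),
        times_min=np.asarray(meta["times_min"], dtype=float),
        pixel_size_um=float(meta["pixel_size_um"]),
        dose_gy=float(meta.get("dose_gy", 0.0)),
    )
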