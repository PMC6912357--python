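"""File formats: cohort CSVs, mask PNGs, polygons and run manifests."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "save_mask_png",
    "load_mask_png",
    "save_polygon",
    "load_polygon",
    "write_manifest",
]

_INT_COLUMNS = ("grade_r1", "grade_r2", "grade_r3")


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort table; floats keep full repr precision (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # shortest decimal that round-trips each float exactly
    cohort.to_csv(path, index=False,
                  float_format=lambda v: np.format_float_positional(v, unique=True))
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(int)
    if "true_id" in df.columns:
        df["true_id"] = df["true_id"].astype(bool)
    return df


def save_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))
    return path


def load_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def save_polygon(vertices, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"vertices": [list(map(float, v)) for v in vertices]}))
    return path


def load_polygon(path: str | Path) -> list[tuple[float, float]]:
    data = json.loads(Path(path).read_text())
    return [tuple(v) for v in data["vertices"]]


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> Path:
    """Record everything needed to reproduce a run bit-for-bit."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "bluesclera_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
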