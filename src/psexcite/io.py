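"""File writers shared by the CLI subcommands.

CSV profiles keep full float precision; intensity maps go out as 32-bit
float TIFF (raw values) plus 8-bit PNG (peak-normalized, for quick
inspection).  Every run writes a JSON manifest echoing the effective
parameters and seed, sufficient to reproduce the outputs bitwise.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .beams import RadialProfile

__all__ = [
    "write_profile_csv",
    "write_columns_csv",
    "write_map_tiff",
    "write_map_png",
    "write_metrics_json",
    "write_manifest",
]


def write_profile_csv(profile: RadialProfile, path, header=("radius", "intensity")) -> Path:
    """Write a radius/intensity profile; full repr precision, roundtrip-safe."""
    return write_columns_csv({header[0]: profile.radii, header[1]: profile.values}, path)


def write_columns_csv(columns: dict, path) -> Path:
    path = Path(path)
    names = list(columns)
    arrays = [np.asarray(columns[k], dtype=float) for k in names]
    if not arrays or arrays[0].size == 0:
        raise ValueError(f"refusing to write empty table to {path}")
    if any(a.shape != arrays[0].shape for a in arrays):
        raise ValueError("all columns must have the same length")
    try:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(names)
            for row in zip(*arrays):
                w.writerow([repr(float(v)) for v in row])
    except OSError as exc:
        raise OSError(f"failed writing CSV {path}: {exc}") from exc
    return path


def write_map_tiff(values: np.ndarray, path) -> Path:
    path = Path(path)
    try:
        tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    except OSError as exc:
        raise OSError(f"failed writing TIFF {path}: {exc}") from exc
    return path


def write_map_png(values: np.ndarray, path) -> Path:
    """8-bit peak-normalized rendering; all-zero maps come out black."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    peak = values.max()
    scaled = values / peak if peak > 0 else values
    img = (np.clip(scaled, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    try:
        Image.fromarray(img).save(path)
    except OSError as exc:
        raise OSError(f"failed writing PNG {path}: {exc}") from exc
    return path


def write_metrics_json(metrics: dict, path) -> Path:
    path = Path(path)
    try:
        path.write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing JSON {path}: {exc}") from exc
    return path


def write_manifest(params: dict, outdir) -> Path:
    """Record every effective parameter of a run for bitwise reproduction."""
    return write_metrics_json(params, Path(outdir) / "manifest.json")
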