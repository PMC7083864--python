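"""Standard-format input/output: TIFF/PNG images, CSV tables, JSON reports.

Coordinates are 0-based (row, col); ROIs are half-open
[top, top+size) x [left, left+size) windows.  Label maps are written as
16-bit TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_image",
    "write_image",
    "write_labels",
    "read_labels",
    "read_centroids_csv",
    "write_centroids_csv",
    "write_report",
    "read_report",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF or PNG micrograph as float in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]  # first channel of an accidental RGB
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def write_image(path: str | Path, image: np.ndarray, bits: int = 16) -> None:
    """Write a [0, 1] float image as 8- or 16-bit TIFF/PNG."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bits == 8:
        arr = np.round(image * 255).astype(np.uint8)
    elif bits == 16:
        arr = np.round(image * 65535).astype(np.uint16)
    else:
        raise ValueError(f"bits must be 8 or 16, got {bits}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 65535:
        raise ValueError("label values must fit in uint16")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_centroids_csv(path: str | Path,
                        centroids: list[tuple[float, float]]) -> None:
    df = pd.DataFrame(
        {"id": range(len(centroids)),
         "row": [c[0] for c in centroids],
         "col": [c[1] for c in centroids]}
    )
    df.to_csv(path, index=False)


def read_centroids_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    missing = {"row", "col"} - set(df.columns)
    if missing:
        raise ValueError(f"centroid CSV {path} lacks columns: {sorted(missing)}")
    return [(float(r), float(c)) for r, c in zip(df["row"], df["col"])]


def write_report(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
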