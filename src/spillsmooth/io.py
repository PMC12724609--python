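"""Readers and writers for TIFF rasters and CSV cell tables.

Cell tables are CSV files with the header
``image_id,cell_id,area_px,centroid_row,centroid_col,<channels...>,truth_<channels...>``
— one row per cell, ``(image_id, cell_id)`` unique.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import IntensityImage, LabelMask

__all__ = [
    "read_intensity",
    "write_intensity",
    "read_mask",
    "write_mask",
    "read_cell_table",
    "write_cell_table",
    "read_config",
    "write_config",
]

REQUIRED_CELL_COLUMNS = ["image_id", "cell_id", "area_px", "centroid_row", "centroid_col"]


def _load_planes(path: str | os.PathLike) -> np.ndarray:
    """Load a TIFF as a (C, H, W) stack, accepting 2D, multi-page and
    channels-last layouts."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim == 3:
        # channels-last heuristic: small trailing axis, large leading axes
        if arr.shape[2] < min(arr.shape[0], arr.shape[1]) and arr.shape[2] <= 64:
            return np.moveaxis(arr, 2, 0)
        return arr
    raise ValueError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")


def read_intensity(
    path: str | os.PathLike,
    channel: int | str = 0,
    *,
    pixel_size_um: float | None = None,
    channel_names: list[str] | None = None,
) -> IntensityImage:
    """Read one channel of a single- or multi-plane TIFF as an intensity image.

    ``channel`` may be a plane index or, if ``channel_names`` is given, a
    name. Pixel size defaults to 1 μm when no sidecar metadata is supplied.
    """
    planes = _load_planes(path)
    names = channel_names or [str(i) for i in range(planes.shape[0])]
    if isinstance(channel, str):
        if channel not in names:
            raise KeyError(
                f"channel {channel!r} not found in {path}; available: {names}"
            )
        idx = names.index(channel)
    else:
        idx = int(channel)
        if not 0 <= idx < planes.shape[0]:
            raise KeyError(
                f"channel index {idx} out of range for {path}; available: {names}"
            )
    px = pixel_size_um
    if px is None:
        px = _pixel_size_from_sidecar(path)
    pixels = planes[idx].astype(np.float64)
    is_norm = bool(np.any(pixels < 0))
    return IntensityImage(
        pixels,
        pixel_size_um=px if px is not None else 1.0,
        channel_name=str(names[idx]) if channel_names else str(channel),
        is_normalized=is_norm,
    )


def write_intensity(image: IntensityImage, path: str | os.PathLike) -> None:
    """Write an intensity image as float32 TIFF plus a YAML sidecar with
    pixel size and the ``is_normalized`` marker."""
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    _write_sidecar(
        path,
        {
            "pixel_size_um": float(image.pixel_size_um),
            "channel_name": image.channel_name,
            "is_normalized": bool(image.is_normalized),
        },
    )


def _sidecar_path(path: str | os.PathLike) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".yaml")


def _write_sidecar(path: str | os.PathLike, meta: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def _pixel_size_from_sidecar(path: str | os.PathLike) -> float | None:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = yaml.safe_load(fh) or {}
        if "pixel_size_um" in meta:
            return float(meta["pixel_size_um"])
    return None


def read_mask(path: str | os.PathLike, *, pixel_size_um: float | None = None) -> LabelMask:
    """Read an integer-typed TIFF as a label mask; floats are rejected."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"label mask must be 2D, got shape {arr.shape} in {path}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"label mask must be integer-typed, got {arr.dtype} in {path}"
        )
    if arr.min() < 0:
        raise ValueError(f"label mask in {path} contains negative values")
    px = pixel_size_um
    if px is None:
        px = _pixel_size_from_sidecar(path)
    return LabelMask(arr.astype(np.int64), pixel_size_um=px if px is not None else 1.0)


def write_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    labels = mask.labels
    dtype = np.uint16 if labels.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))
    _write_sidecar(path, {"pixel_size_um": float(mask.pixel_size_um)})


def write_cell_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cell table as CSV with full float precision.

    Raises on duplicate ``(image_id, cell_id)`` pairs.
    """
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table is missing required columns: {missing}")
    if table.duplicated(subset=["image_id", "cell_id"]).any():
        raise ValueError("cell table has duplicate (image_id, cell_id) pairs")
    ordered = REQUIRED_CELL_COLUMNS + [
        c for c in table.columns if c not in REQUIRED_CELL_COLUMNS
    ]
    table[ordered].to_csv(path, index=False, float_format="%.17g")


def read_cell_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing required columns: {missing}")
    if table.duplicated(subset=["image_id", "cell_id"]).any():
        raise ValueError(f"cell table {path} has duplicate (image_id, cell_id) pairs")
    return table


def read_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(config: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
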