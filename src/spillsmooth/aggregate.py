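"""Per-cell aggregation and the per-cell / per-image normalization
variants used downstream of any image-level correction.

``mean_aggregate`` is the baseline quantification: the arithmetic mean of
a channel over each cell's mask pixels. The normalizations here operate
on the resulting per-cell values; all of them are monotone within their
group and therefore leave within-image AUROC unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import IntensityImage, LabelMask, check_same_shape

__all__ = [
    "mean_aggregate",
    "asinh_transform",
    "zscore_values",
    "minmax_clip_scale",
    "minmax_per_cell",
    "cell_table_skeleton",
]


def mean_aggregate(
    image: IntensityImage | np.ndarray,
    mask: LabelMask | np.ndarray,
    cell_ids: np.ndarray | None = None,
) -> pd.Series:
    """Mean intensity per cell, indexed by cell id.

    ``cell_ids`` restricts (and orders) the output; an id absent from the
    mask is an error naming the id.
    """
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if isinstance(image, IntensityImage) and isinstance(mask, LabelMask):
        check_same_shape(image, mask)
    elif pixels.shape != labels.shape:
        raise ValueError(f"shape mismatch: {pixels.shape} vs {labels.shape}")
    present = np.unique(labels)
    present = present[present > 0]
    if cell_ids is None:
        cell_ids = present
    else:
        cell_ids = np.asarray(cell_ids)
        missing = np.setdiff1d(cell_ids, present)
        if missing.size:
            raise KeyError(f"cell id(s) {missing.tolist()} absent from mask")
    if len(cell_ids) == 0:
        return pd.Series(dtype=float, name="intensity")
    means = ndimage.mean(pixels, labels=labels, index=cell_ids)
    return pd.Series(means, index=pd.Index(cell_ids, name="cell_id"), name="intensity")


def asinh_transform(values, cofactor: float = 50.0):
    """Elementwise ``asinh(v / cofactor)`` — the standard variance-
    stabilizing transform for cytometry intensities."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    return np.arcsinh(np.asarray(values, dtype=np.float64) / cofactor)


def zscore_values(values):
    """Standardize with the population standard deviation; a constant
    group yields zeros with a warning rather than NaNs."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("z-score needs at least 2 values")
    sd = v.std()
    if sd == 0:
        warnings.warn("constant values: z-scores set to zero", stacklevel=2)
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def minmax_clip_scale(values, q_low: float = 1.0, q_high: float = 99.0):
    """Clip to the [q_low, q_high] percentiles (linear interpolation) and
    rescale to [0, 1]. Applied per image or per batch by the caller's
    grouping."""
    if not q_low < q_high:
        raise ValueError("q_low must be < q_high")
    v = np.asarray(values, dtype=np.float64)
    lo, hi = np.percentile(v, [q_low, q_high])
    clipped = np.clip(v, lo, hi)
    if hi == lo:
        warnings.warn("degenerate range after clipping: values set to zero", stacklevel=2)
        return np.zeros_like(v)
    return (clipped - lo) / (hi - lo)


def minmax_per_cell(table: pd.DataFrame, channels: list[str]) -> pd.DataFrame:
    """Scale each cell's channel vector to [0, 1] by its own min/max
    (the 'mean_scaled' variant). Flat vectors become zeros with a warning."""
    if len(channels) < 2:
        raise ValueError("per-cell min-max needs at least 2 channels")
    out = table.copy()
    block = out[channels].to_numpy(dtype=np.float64)
    lo = block.min(axis=1, keepdims=True)
    hi = block.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} cell(s) with flat channel vectors set to zero",
            stacklevel=2,
        )
    span[span == 0] = 1.0
    scaled = (block - lo) / span
    scaled[flat] = 0.0
    out[channels] = scaled
    return out


def cell_table_skeleton(mask: LabelMask, image_id: str = "img0") -> pd.DataFrame:
    """Per-cell id / area / centroid table from a label mask (no
    intensities yet)."""
    labels = mask.labels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(
            columns=["image_id", "cell_id", "area_px", "centroid_row", "centroid_col"]
        )
    areas = ndimage.sum_labels(np.ones_like(labels), labels=labels, index=ids)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels=labels, index=ids)
    rows, cols = zip(*centroids)
    return pd.DataFrame(
        {
            "image_id": image_id,
            "cell_id": ids.astype(int),
            "area_px": areas.astype(int),
            "centroid_row": rows,
            "centroid_col": cols,
        }
    )
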