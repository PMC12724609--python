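"""Core raster and table data model.

The package works on three in-memory containers:

* :class:`IntensityImage` — one channel of a multiplexed acquisition as a
  2D nonnegative raster (raw ion counts, or real values after
  normalization), together with the physical pixel size.
* :class:`LabelMask` — an integer segmentation mask of identical shape,
  0 meaning background and positive integers meaning cell ids.
* cell tables — plain :class:`pandas.DataFrame` objects with one row per
  cell (see :mod:`spillsmooth.io` for the on-disk schema).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntensityImage", "LabelMask", "RunConfig"]


@dataclass
class IntensityImage:
    """A single-channel 2D intensity raster.

    Parameters
    ----------
    pixels
        ``(H, W)`` array of finite reals. Raw counts must be nonnegative;
        normalized images (``is_normalized=True``) may contain negatives.
    pixel_size_um
        Physical edge length of one pixel in micrometers.
    channel_name
        Marker / channel identifier.
    is_normalized
        Set by normalization steps (e.g. GZ) whose output is no longer a
        count image.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    channel_name: str = ""
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("intensity image must be a nonempty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensity image contains non-finite values")
        if not self.is_normalized and np.any(self.pixels < 0):
            raise ValueError("raw intensity image contains negative values")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """An integer segmentation mask; 0 = background, >0 = cell ids.

    Cell ids need not be contiguous. Pairs with an :class:`IntensityImage`
    of identical shape.
    """

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("label mask must have an integer dtype")
        if labels.ndim != 2 or labels.size == 0:
            raise ValueError("label mask must be a nonempty 2D array")
        if labels.min() < 0:
            raise ValueError("label mask contains negative labels")
        self.labels = labels
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cell_ids(self) -> np.ndarray:
        """Sorted array of the positive labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class RunConfig:
    """Seed plus named parameter groups for a reproducible run.

    The single ``seed`` fully determines every stochastic operation; named
    stage seeds are derived from it (:func:`spillsmooth.cli.seed_stream`).
    """

    seed: int = 0
    gz: dict = field(default_factory=dict)
    sci: dict = field(default_factory=dict)
    rati: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    eval: dict = field(default_factory=dict)


def check_same_shape(image: IntensityImage, mask: LabelMask) -> None:
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} does not match mask shape {mask.shape}"
        )
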