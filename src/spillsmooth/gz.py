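"""Getis-Ord G* image normalization (GZ) and blur baselines.

The local Getis-Ord G* statistic measures spatial clustering of high or
low values around a pixel. Its standardized form,

    GZ_i = (Σ_{j∈N(i)} x_j − X̄·W_i) / ( S · sqrt( (n·W_i − W_i²)/(n−1) ) ),

with X̄ the image mean, S the population standard deviation, n the pixel
count and W_i the number of in-image neighbors of pixel i, has mean 0 and
variance ≈ 1 under spatial randomness. Applied per pixel it acts as local
smoothing plus a per-image standardization, which is what makes it useful
both as a pre-aggregation smoother and as an image-level batch
normalization: GZ is exactly invariant to affine rescaling ``x → c·x + a``
of the input image.

The default neighborhood is the 3×3 "queen" window (Euclidean distance
< 1.5, focal pixel included). With the focal pixel included and away from
image borders, GZ is a positive affine transform of the 3×3 box sum, so
per-cell mean aggregation of GZ and of a 3×3 box blur rank cells
identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import IntensityImage

__all__ = [
    "NeighborhoodSpec",
    "GZField",
    "neighbor_offsets",
    "getis_ord_raw",
    "gz_normalize",
    "box_blur",
    "gaussian_blur",
    "gaussian_kernel_1d",
    "auto_sigma",
]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Binary spatial weights: all integer offsets with Euclidean norm
    strictly below ``distance_threshold``; the focal pixel is included iff
    ``include_self`` (default, the conventional G* form)."""

    distance_threshold: float = 1.5
    include_self: bool = True


@dataclass
class GZField:
    """Result of a GZ pass: the standardized field plus the source-image
    statistics it was standardized with."""

    values: np.ndarray
    spec: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)
    n: int = 0
    mean: float = 0.0
    sd: float = 0.0
    degenerate: bool = False

    def as_image(self, template: IntensityImage | None = None) -> IntensityImage:
        px = template.pixel_size_um if template is not None else 1.0
        name = template.channel_name if template is not None else ""
        return IntensityImage(
            self.values, pixel_size_um=px, channel_name=name, is_normalized=True
        )


def neighbor_offsets(spec: NeighborhoodSpec) -> list[tuple[int, int]]:
    """All integer ``(dr, dc)`` offsets with ``hypot(dr, dc) <
    distance_threshold``, lexicographically sorted."""
    d = spec.distance_threshold
    if d <= 0:
        raise ValueError("distance_threshold must be > 0")
    r = int(math.ceil(d))
    offsets = []
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if dr == 0 and dc == 0:
                if spec.include_self:
                    offsets.append((0, 0))
                continue
            if math.hypot(dr, dc) < d:
                offsets.append((dr, dc))
    offsets.sort()
    return offsets


def _neighbor_kernel(spec: NeighborhoodSpec) -> np.ndarray:
    offsets = neighbor_offsets(spec)
    r = max(max(abs(dr), abs(dc)) for dr, dc in offsets) if offsets else 0
    k = np.zeros((2 * r + 1, 2 * r + 1))
    for dr, dc in offsets:
        k[dr + r, dc + r] = 1.0
    return k


def _neighbor_sums(pixels: np.ndarray, spec: NeighborhoodSpec):
    """Neighbor sum and in-image neighbor count per pixel (out-of-image
    neighbors dropped, no padding)."""
    kernel = _neighbor_kernel(spec)
    nsum = ndimage.correlate(pixels, kernel, mode="constant", cval=0.0)
    w = ndimage.correlate(np.ones_like(pixels), kernel, mode="constant", cval=0.0)
    return nsum, np.rint(w)


def getis_ord_raw(image: IntensityImage, spec: NeighborhoodSpec | None = None) -> GZField:
    """Unstandardized G*: neighbor sum divided by the image total."""
    spec = spec or NeighborhoodSpec()
    x = image.pixels
    if np.any(x < 0):
        raise ValueError("raw G* requires a nonnegative image")
    total = x.sum()
    if total <= 0:
        raise ValueError("raw G* undefined for an all-zero image")
    nsum, _ = _neighbor_sums(x, spec)
    return GZField(
        nsum / total, spec=spec, n=x.size, mean=float(x.mean()), sd=float(x.std())
    )


def gz_normalize(image: IntensityImage, spec: NeighborhoodSpec | None = None) -> GZField:
    """Standardized Getis-Ord G* per pixel (GZ normalization).

    Uses population (divide-by-n) mean and standard deviation over the
    whole image. A constant image (S = 0) has no spatial structure and
    yields an all-zero field with ``degenerate=True`` plus a warning;
    a single-pixel image is an error.
    """
    spec = spec or NeighborhoodSpec()
    x = np.asarray(image.pixels, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("GZ normalization needs at least 2 pixels")
    xbar = x.mean()
    s = math.sqrt(max((x * x).mean() - xbar * xbar, 0.0))
    if s == 0.0:
        warnings.warn("constant image: GZ field set to zero", stacklevel=2)
        return GZField(
            np.zeros_like(x), spec=spec, n=n, mean=float(xbar), sd=0.0, degenerate=True
        )
    nsum, w = _neighbor_sums(x, spec)
    denom = s * np.sqrt((n * w - w * w) / (n - 1))
    values = (nsum - xbar * w) / denom
    return GZField(values, spec=spec, n=n, mean=float(xbar), sd=float(s))


def box_blur(image: IntensityImage, k: int = 3) -> IntensityImage:
    """Mean over the k×k window; at borders the mean is taken over the
    in-image pixels only (renormalized), so a constant image is unchanged."""
    if k < 1 or k % 2 == 0:
        raise ValueError("box kernel size must be odd and >= 1")
    x = image.pixels
    kernel = np.ones((k, k))
    num = ndimage.correlate(x, kernel, mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(x), kernel, mode="constant", cval=0.0)
    return IntensityImage(
        num / den,
        pixel_size_um=image.pixel_size_um,
        channel_name=image.channel_name,
        is_normalized=image.is_normalized,
    )


def auto_sigma(k: int) -> float:
    """Default Gaussian sigma for a k×k kernel: ``0.3·((k−1)/2 − 1) + 0.8``."""
    return 0.3 * ((k - 1) / 2 - 1) + 0.8


def gaussian_kernel_1d(k: int, sigma: float | None = None) -> np.ndarray:
    """Length-k Gaussian kernel truncated to the window and renormalized
    to sum 1."""
    if k < 1 or k % 2 == 0:
        raise ValueError("gaussian kernel size must be odd and >= 1")
    if sigma is None:
        sigma = auto_sigma(k)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = (k - 1) // 2
    xs = np.arange(-r, r + 1, dtype=np.float64)
    kern = np.exp(-(xs * xs) / (2.0 * sigma * sigma))
    return kern / kern.sum()


def gaussian_blur(
    image: IntensityImage, k: int = 5, sigma: float | None = None
) -> IntensityImage:
    """Separable truncated-Gaussian blur; borders renormalized over the
    in-image support so constants are preserved."""
    kern = gaussian_kernel_1d(k, sigma)
    x = image.pixels
    num = _separable(x, kern)
    den = _separable(np.ones_like(x), kern)
    return IntensityImage(
        num / den,
        pixel_size_um=image.pixel_size_um,
        channel_name=image.channel_name,
        is_normalized=image.is_normalized,
    )


def _separable(x: np.ndarray, kern: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(x, kern, axis=0, mode="constant", cval=0.0)
    return ndimage.correlate1d(out, kern, axis=1, mode="constant", cval=0.0)
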