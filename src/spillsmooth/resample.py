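"""Mask resampling (RATI) and segmentation-perturbation utilities.

RATI (random affine transformation intensity) treats the segmentation
mask as uncertain: the mask is resampled many times by perturbing every
cell with a small random affine transform, each resampled mask is
mean-aggregated, and the per-cell median over iterations is the final
intensity. With degenerate (identity) parameter ranges it reduces
bit-exactly to plain mean aggregation. The per-cell iteration standard
deviation is emitted as a missegmentation diagnostic.

The perturbation utilities simulate segmentation error: quadrant-wise
dilation/erosion of single cells (dilation overwrites neighbours —
this is what creates spillover in dense tissue), and whole-mask
under-/over-segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import IntensityImage, LabelMask, check_same_shape
from .morphology import SQUARE3, iter_objects, erode_cells, dilate_cells
from .aggregate import mean_aggregate

__all__ = [
    "AffineRanges",
    "RATIParams",
    "random_affine_cell",
    "resample_mask",
    "rati",
    "perturb_single_cells",
    "undersegment",
    "oversegment",
]


@dataclass(frozen=True)
class AffineRanges:
    """Uniform sampling intervals for the per-cell affine draw; all
    parameters drawn independently per cell per iteration."""

    scale: tuple[float, float] = (0.8, 1.2)
    translation_px: tuple[float, float] = (-1.0, 1.0)
    shear: tuple[float, float] = (-0.1, 0.1)
    rotation_deg: tuple[float, float] = (-15.0, 15.0)

    def __post_init__(self):
        for name in ("scale", "translation_px", "shear", "rotation_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval has low > high")

    @classmethod
    def identity(cls) -> "AffineRanges":
        return cls((1.0, 1.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0))


@dataclass(frozen=True)
class RATIParams:
    n_iterations: int = 25
    ranges: AffineRanges = field(default_factory=AffineRanges)
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def _draw_affine(ranges: AffineRanges, rng: np.random.Generator):
    scale = rng.uniform(*ranges.scale)
    t = rng.uniform(ranges.translation_px[0], ranges.translation_px[1], size=2)
    shear = rng.uniform(*ranges.shear)
    rot = np.deg2rad(rng.uniform(*ranges.rotation_deg))
    # forward linear map = rotate ∘ shear ∘ scale, about the cell centroid
    s_m = np.array([[scale, 0.0], [0.0, scale]])
    sh_m = np.array([[1.0, shear], [0.0, 1.0]])
    c, s = np.cos(rot), np.sin(rot)
    r_m = np.array([[c, -s], [s, c]])
    return r_m @ sh_m @ s_m, t


def _warp_coords(
    coords: np.ndarray,
    matrix: np.ndarray,
    translation: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    """Inverse-warp a binary footprint given forward affine about its
    centroid; returns the transformed (row, col) pixel set."""
    centroid = coords.mean(axis=0)
    inv = np.linalg.inv(matrix)
    # candidate output region: forward image of the bbox corners, padded
    fwd = (coords - centroid) @ matrix.T + centroid + translation
    r0 = max(int(np.floor(fwd[:, 0].min())) - 1, 0)
    r1 = min(int(np.ceil(fwd[:, 0].max())) + 2, shape[0])
    c0 = max(int(np.floor(fwd[:, 1].min())) - 1, 0)
    c1 = min(int(np.ceil(fwd[:, 1].max())) + 2, shape[1])
    if r1 <= r0 or c1 <= c0:
        return np.empty((0, 2), dtype=np.int64)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    cand = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    src = (cand - centroid - translation) @ inv.T + centroid
    src = np.rint(src).astype(np.int64)
    # membership lookup in the original footprint
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    lut = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    lut[coords[:, 0] - rmin, coords[:, 1] - cmin] = True
    ok = (
        (src[:, 0] >= rmin) & (src[:, 0] <= rmax)
        & (src[:, 1] >= cmin) & (src[:, 1] <= cmax)
    )
    hit = np.zeros(len(cand), dtype=bool)
    hit[ok] = lut[src[ok, 0] - rmin, src[ok, 1] - cmin]
    return cand[hit].astype(np.int64)


def random_affine_cell(
    cell_pixels: np.ndarray,
    ranges: AffineRanges,
    rng: np.random.Generator,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Randomly affine-transform one cell's pixel set about its centroid.

    ``cell_pixels`` is an (N, 2) array of (row, col) coordinates; the
    result is the nearest-neighbor inverse-warped footprint (possibly
    empty if mapped outside the image)."""
    coords = np.asarray(cell_pixels, dtype=np.int64)
    if coords.size == 0:
        raise ValueError("cell has no pixels")
    if shape is None:
        shape = (int(coords[:, 0].max()) + 3, int(coords[:, 1].max()) + 3)
    matrix, t = _draw_affine(ranges, rng)
    return _warp_coords(coords, matrix, t, shape)


def resample_mask(
    mask: LabelMask, ranges: AffineRanges, rng: np.random.Generator
) -> LabelMask:
    """One resampled mask: cells visited in random order, each stamped
    onto a fresh canvas (later cells overwrite earlier ones), then gaps
    that were foreground in the original are closed per cell (3×3
    closing, claiming only still-background pixels, same visit order)."""
    labels = mask.labels
    shape = labels.shape
    cells = {cid: sl for cid, sl in iter_objects(labels)}
    order = rng.permutation(np.array(sorted(cells), dtype=np.int64))
    canvas = np.zeros_like(labels)
    for cid in order:
        sl = cells[cid]
        local = np.argwhere(labels[sl] == cid)
        coords = local + np.array([sl[0].start, sl[1].start])
        new = random_affine_cell(coords, ranges, rng, shape)
        if len(new):
            canvas[new[:, 0], new[:, 1]] = cid
    # close gaps: background now, foreground before
    gaps = (canvas == 0) & (labels > 0)
    if gaps.any():
        for cid in order:
            fp = canvas == cid
            if not fp.any():
                continue
            sl = ndimage.find_objects(fp.astype(np.int8))[0]
            psl = (
                slice(max(sl[0].start - 2, 0), min(sl[0].stop + 2, shape[0])),
                slice(max(sl[1].start - 2, 0), min(sl[1].stop + 2, shape[1])),
            )
            closed = ndimage.binary_closing(fp[psl], structure=SQUARE3)
            claim = closed & ~fp[psl] & gaps[psl] & (canvas[psl] == 0)
            canvas[psl][claim] = cid
    return LabelMask(canvas, pixel_size_um=mask.pixel_size_um)


def rati(
    image: IntensityImage, mask: LabelMask, params: RATIParams | None = None
) -> pd.DataFrame:
    """Median-of-resampled-means intensity per cell.

    Returns a table indexed by cell id with columns ``intensity`` (the
    RATI value), ``iteration_sd`` (diagnostic spread over iterations),
    ``n_present`` and ``fallback`` (True for cells absent from every
    resampled mask, which fall back to the original-mask mean)."""
    params = params or RATIParams()
    check_same_shape(image, mask)
    rng = np.random.default_rng(params.seed)
    base = mean_aggregate(image, mask)
    ids = base.index.to_numpy()
    pos = {cid: i for i, cid in enumerate(ids)}
    values = np.full((params.n_iterations, len(ids)), np.nan)
    for it in range(params.n_iterations):
        m = resample_mask(mask, params.ranges, rng)
        means = mean_aggregate(image, m)
        for cid, v in means.items():
            if cid in pos:
                values[it, pos[cid]] = v
    n_present = np.sum(~np.isnan(values), axis=0)
    with np.errstate(all="ignore"):
        med = np.nanmedian(values, axis=0)
        sd = np.nanstd(values, axis=0)
    fallback = n_present == 0
    med[fallback] = base.to_numpy()[fallback]
    sd[fallback] = np.nan
    return pd.DataFrame(
        {
            "intensity": med,
            "iteration_sd": sd,
            "n_present": n_present,
            "fallback": fallback,
        },
        index=pd.Index(ids, name="cell_id"),
    )


_QUADRANTS = ("top_left", "top_right", "bottom_left", "bottom_right")


def _quadrant_mask(
    shape: tuple[int, int], origin: tuple[int, int], centroid: tuple[float, float],
    quadrant: str,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    rr = rr + origin[0]
    cc = cc + origin[1]
    top = rr <= centroid[0]
    left = cc <= centroid[1]
    return {
        "top_left": top & left,
        "top_right": top & ~left,
        "bottom_left": ~top & left,
        "bottom_right": ~top & ~left,
    }[quadrant]


def perturb_single_cells(
    mask: LabelMask,
    n_cells: int,
    rng: np.random.Generator,
    ops: tuple[str, ...] = ("dilate", "erode"),
    ranges_px: tuple[int, ...] = (1, 2),
) -> tuple[LabelMask, pd.DataFrame]:
    """Quadrant-wise dilation/erosion of randomly sampled single cells.

    For each of ``n_cells`` cells (sampled without replacement) an
    operation, a quadrant relative to the cell centroid and a range (px)
    are drawn uniformly. Erosion turns the cell's eroded-away pixels in
    that quadrant into background; dilation adds a range-thick rim in
    that quadrant, *overwriting* neighbouring labels — which is what
    creates spillover in dense tissue. Returns the perturbed mask and a
    record table (cell_id, op, quadrant, range_px) so evaluation can be
    restricted to the modified cells."""
    labels = mask.labels.copy()
    cells = {cid: sl for cid, sl in iter_objects(mask.labels)}
    ids = np.array(sorted(cells), dtype=np.int64)
    if n_cells > len(ids):
        raise ValueError(f"n_cells={n_cells} exceeds cell count {len(ids)}")
    chosen = rng.choice(ids, size=n_cells, replace=False)
    records = []
    for cid in chosen:
        op = ops[rng.integers(len(ops))]
        quadrant = _QUADRANTS[rng.integers(4)]
        px = int(ranges_px[rng.integers(len(ranges_px))])
        sl = cells[cid]
        psl = (
            slice(max(sl[0].start - px, 0), min(sl[0].stop + px, labels.shape[0])),
            slice(max(sl[1].start - px, 0), min(sl[1].stop + px, labels.shape[1])),
        )
        crop = labels[psl] == cid
        coords = np.argwhere(crop)
        centroid = coords.mean(axis=0) + np.array([psl[0].start, psl[1].start])
        quad = _quadrant_mask(crop.shape, (psl[0].start, psl[1].start),
                              tuple(centroid), quadrant)
        if op == "erode":
            eroded = ndimage.binary_erosion(
                crop, structure=SQUARE3, iterations=px, border_value=0
            )
            removed = crop & ~eroded & quad
            labels[psl][removed] = 0
        else:
            grown = ndimage.binary_dilation(crop, structure=SQUARE3, iterations=px)
            gained = grown & ~crop & quad
            labels[psl][gained] = cid
        records.append((int(cid), op, quadrant, px))
    table = pd.DataFrame(records, columns=["cell_id", "op", "quadrant", "range_px"])
    return LabelMask(labels, pixel_size_um=mask.pixel_size_um), table


def undersegment(mask: LabelMask, px: int) -> LabelMask:
    """Whole-mask undersegmentation: every cell eroded by ``px`` 3×3
    steps; cells eroded to empty vanish."""
    if px not in (1, 2):
        raise ValueError("px must be 1 or 2")
    return erode_cells(mask, px)


def oversegment(mask: LabelMask, px: int) -> LabelMask:
    """Whole-mask oversegmentation: every cell dilated by ``px`` steps
    claiming only background (ascending-id visit order), so in densely
    packed tissue only image-border cells can actually grow."""
    if px not in (1, 2):
        raise ValueError("px must be 1 or 2")
    return dilate_cells(mask, px)
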