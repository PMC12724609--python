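"""Per-cell mask morphology.

All operations treat each labelled cell independently, so touching cells
each keep their own boundary ring / eroded core — a whole-mask binary
erosion would merge their borders.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import LabelMask

__all__ = ["boundary_mask", "erode_cells", "dilate_cells"]

# 3x3 square structuring element used throughout
SQUARE3 = np.ones((3, 3), dtype=bool)


def iter_objects(labels: np.ndarray):
    """Yield ``(cell_id, bounding slice)`` for every positive label,
    ascending, including non-contiguous ids."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return
    objects = ndimage.find_objects(labels, max_label=int(ids.max()))
    for cid in ids:
        sl = objects[cid - 1]
        if sl is not None:
            yield int(cid), sl


def padded_slice(sl: tuple[slice, slice], shape: tuple[int, int], pad: int):
    r0 = max(sl[0].start - pad, 0)
    r1 = min(sl[0].stop + pad, shape[0])
    c0 = max(sl[1].start - pad, 0)
    c1 = min(sl[1].stop + pad, shape[1])
    return slice(r0, r1), slice(c0, c1)


def boundary_labels(labels: np.ndarray) -> np.ndarray:
    """Array-level :func:`boundary_mask` (used by the simulator on stacks)."""
    out = np.zeros_like(labels)
    for cid, sl in iter_objects(labels):
        crop = labels[sl] == cid
        eroded = ndimage.binary_erosion(crop, structure=SQUARE3, border_value=0)
        ring = crop & ~eroded
        out[sl][ring] = cid
    return out


def boundary_mask(mask: LabelMask) -> LabelMask:
    """Boundary ring of every cell: cell pixels minus the 3×3 erosion of
    that cell alone.

    Cells of width or height ≤ 2 erode to nothing and are entirely
    boundary. Labels are preserved on surviving boundary pixels.
    """
    return LabelMask(boundary_labels(mask.labels), pixel_size_um=mask.pixel_size_um)


def erode_cells(mask: LabelMask, px: int = 1) -> LabelMask:
    """Erode every cell independently by ``px`` applications of the 3×3
    element; cells eroded to empty vanish from the output."""
    if px < 0:
        raise ValueError("px must be >= 0")
    labels = mask.labels
    out = np.zeros_like(labels)
    for cid, sl in iter_objects(labels):
        crop = labels[sl] == cid
        if px > 0:
            crop = ndimage.binary_erosion(
                crop, structure=SQUARE3, iterations=px, border_value=0
            )
        out[sl][crop] = cid
    return LabelMask(out, pixel_size_um=mask.pixel_size_um)


def dilate_cells(mask: LabelMask, px: int = 1) -> LabelMask:
    """Dilate every cell by ``px`` 3×3 steps, claiming only background.

    Cells are visited in ascending id order; contested background pixels
    go to the first claimant, and no pixel ever changes from one positive
    label to another.
    """
    if px < 0:
        raise ValueError("px must be >= 0")
    labels = mask.labels
    out = labels.copy()
    shape = labels.shape
    for cid, sl in iter_objects(labels):
        psl = padded_slice(sl, shape, px)
        crop = labels[psl] == cid
        grown = ndimage.binary_dilation(crop, structure=SQUARE3, iterations=px)
        gained = grown & ~crop & (out[psl] == 0)
        out[psl][gained] = cid
    return LabelMask(out, pixel_size_um=mask.pixel_size_um)
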