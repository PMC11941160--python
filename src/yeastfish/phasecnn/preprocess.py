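"""Per-cell composite construction for the classifier.

Each cell (plus its linked bud or mother) is cropped from the brightfield,
SPB-marker and DAPI stacks, reduced to 2-D by a standard-deviation
projection along z (moving emitters and rims have high variance, flat
background does not), SPB local-thresholded to isolate the marker dots,
overlaid with the segmentation boundary to mark the cell of interest, and
resized/padded to 80 x 80 with per-channel min-max normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import find_boundaries
from skimage.transform import resize

from yeastfish.cellgeom import _crop_bbox


@dataclass
class CellComposite:
    image: np.ndarray  # (size, size, 3) float32 in [0, 1]; (BF, SPB, DAPI)
    cell_id: int
    label: str | None = None  # ground-truth phase if known


def _std_projection(stack: np.ndarray) -> np.ndarray:
    return np.asarray(stack, dtype=np.float64).std(axis=0)


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img, dtype=np.float32)
    return ((img - lo) / (hi - lo)).astype(np.float32)


def preprocess_cell(
    stacks: dict[str, np.ndarray],
    label_mask: np.ndarray,
    cell_id: int,
    partner_id: int | None = None,
    size: int = 80,
    margin: int = 4,
    spb_k: float = 5.0,
    phase: str | None = None,
) -> CellComposite:
    """Build the (size x size x 3) composite for one cell.

    ``partner_id`` is the linked bud (for mothers) or mother (for buds) so
    the pair appears in one frame.  Channel order is (BF, SPB, DAPI).
    """
    for ch in ("BF", "SPB", "DAPI"):
        if ch not in stacks:
            raise ValueError(f"missing {ch!r} stack")
    labels = [cell_id] + ([partner_id] if partner_id else [])
    own = np.isin(label_mask, labels)
    if own.sum() < 4:
        raise ValueError(f"degenerate mask for cell {cell_id} (<4 px)")
    box = _crop_bbox(label_mask, labels, pad=margin)
    # the overlay marks the cell of interest only — a bud and its mother
    # share the frame but get different contours, which is what lets the
    # classifier separate X from X-Bud
    own_boundary = find_boundaries(label_mask[box] == cell_id, mode="inner")

    planes = []
    for ch in ("BF", "SPB", "DAPI"):
        proj = _std_projection(np.asarray(stacks[ch])[:, box[0], box[1]])
        if ch == "SPB":
            thr = proj.mean() + spb_k * proj.std()
            proj = np.where(proj > thr, proj, 0.0)
        peak = proj.max() if proj.max() > 0 else 1.0
        proj = proj.copy()
        proj[own_boundary] = peak
        planes.append(proj)

    h, w = planes[0].shape
    side = max(h, w)
    squared = []
    for proj in planes:
        canvas = np.zeros((side, side), dtype=np.float64)
        y0, x0 = (side - h) // 2, (side - w) // 2
        canvas[y0 : y0 + h, x0 : x0 + w] = proj
        if side > size:
            canvas = resize(canvas, (size, size), order=1, anti_aliasing=True)
        elif side < size:
            pad0 = (size - side) // 2
            big = np.zeros((size, size), dtype=np.float64)
            big[pad0 : pad0 + side, pad0 : pad0 + side] = canvas
            canvas = big
        squared.append(_minmax(canvas))
    image = np.stack(squared, axis=-1).astype(np.float32)
    return CellComposite(image=image, cell_id=int(cell_id), label=phase)
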