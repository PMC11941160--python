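"""Per-cell geometry and marker features.

Extracts, for every label of a 2-D segmentation mask: area, centroid,
spindle-pole-body (SPB) count from the marker channel, bud-mother links
from size ratio + adjacency, and DAPI nuclear morphology (blob count,
elongation, whether the stained region spans the bud neck).  These features
feed the deterministic phase rule and the CNN preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

from yeastfish.optics import OpticsConfig


@dataclass
class DapiFeatures:
    n_blobs: int = 0
    elongation: float = 1.0  # major / minor axis of the largest blob
    crosses_neck: bool = False
    flagged: bool = False  # no usable DAPI signal


@dataclass
class CellRecord:
    cell_id: int  # mask label
    area_px: float
    area_um2: float
    centroid: tuple[float, float]
    is_bud: bool = False
    mother_id: int | None = None
    bud_id: int | None = None
    spb_count: int = 0  # capped at 2
    spb_raw: int = 0  # uncapped component count
    spb_flagged: bool = False  # raw count exceeded 2
    dapi: DapiFeatures = field(default_factory=DapiFeatures)
    phase: str | None = None
    strain_id: str = "WT"


def _crop_bbox(mask: np.ndarray, labels: Sequence[int], pad: int = 2):
    sel = np.isin(mask, labels)
    if not sel.any():
        return None
    ys, xs = np.nonzero(sel)
    y0, y1 = max(0, ys.min() - pad), min(mask.shape[0], ys.max() + pad + 1)
    x0, x1 = max(0, xs.min() - pad), min(mask.shape[1], xs.max() + pad + 1)
    return (slice(y0, y1), slice(x0, x1))


def count_spbs(
    spb_stack: np.ndarray,
    label_mask: np.ndarray,
    cell_id: int,
    k: float = 5.0,
) -> tuple[int, int, bool]:
    """SPB count inside one cell: (capped count, raw count, flagged).

    Max-projects the marker stack over z, thresholds the cell's crop at
    local mean + k * local sd, and counts connected bright components that
    overlap the cell's own mask pixels.  Counts above 2 are capped (two
    spindle poles is the biological maximum; more means noise or debris)
    and flagged.
    """
    box = _crop_bbox(label_mask, [cell_id])
    if box is None:
        return 0, 0, False
    proj = np.max(np.asarray(spb_stack, dtype=np.float64), axis=0)[box]
    own = label_mask[box] == cell_id
    thr = proj.mean() + k * proj.std()
    bright = proj > thr
    if not bright.any():
        return 0, 0, False
    comp, n = ndimage.label(bright)
    raw = 0
    for i in range(1, n + 1):
        if (own & (comp == i)).any():
            raw += 1
    return min(raw, 2), raw, raw > 2


def link_buds(
    records: Sequence[CellRecord],
    label_mask: np.ndarray,
    size_ratio: float = 0.5,
    dilation_px: int = 2,
) -> list[CellRecord]:
    """Set ``is_bud`` / ``mother_id`` by size ratio and mask adjacency.

    A cell is a bud candidate for a neighbor when its area is below
    ``size_ratio`` times the neighbor's and the two masks touch within
    ``dilation_px``.  Each bud links to its largest admissible neighbor;
    ties go to the longest shared boundary.  Similar-sized touching cells
    are left unlinked.
    """
    by_id = {r.cell_id: r for r in records}
    structure = np.ones((3, 3), dtype=bool)
    contact: dict[int, dict[int, int]] = {}
    for r in records:
        own = label_mask == r.cell_id
        grown = ndimage.binary_dilation(own, structure, iterations=dilation_px)
        neigh = label_mask[grown & ~own]
        neigh = neigh[neigh > 0]
        labs, counts = np.unique(neigh, return_counts=True)
        contact[r.cell_id] = {
            int(l): int(c) for l, c in zip(labs, counts) if int(l) in by_id
        }
    for r in records:
        candidates = [
            (by_id[l].area_px, contact[r.cell_id][l], l)
            for l in contact[r.cell_id]
            if r.area_px < size_ratio * by_id[l].area_px
        ]
        if not candidates:
            r.is_bud, r.mother_id = False, None
            continue
        candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
        r.is_bud = True
        r.mother_id = candidates[0][2]
        by_id[r.mother_id].bud_id = r.cell_id
    return list(records)


def dapi_features(
    dapi_stack: np.ndarray,
    label_mask: np.ndarray,
    cell_id: int,
    mother_link: int | None = None,
    rel_threshold: float = 0.3,
    min_contrast: float = 20.0,
    min_blob_px: int = 4,
) -> DapiFeatures:
    """Nuclear morphology inside a cell (and its linked bud/mother).

    Thresholds the z-max projection at ``vmin + rel_threshold * (vmax -
    vmin)`` within the union footprint; blobs are connected components of
    at least ``min_blob_px`` pixels.  ``crosses_neck`` is true when one
    blob has pixels in both the mother and the partner label.
    """
    labels = [cell_id] + ([mother_link] if mother_link else [])
    box = _crop_bbox(label_mask, labels)
    if box is None:
        return DapiFeatures(flagged=True)
    proj = np.max(np.asarray(dapi_stack, dtype=np.float64), axis=0)[box]
    # dilate the footprint so a nucleus stretched through the bud neck is
    # not cut in two by the unlabeled gap between mother and bud masks
    region = ndimage.binary_dilation(np.isin(label_mask[box], labels), iterations=3)
    vals = proj[region]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax - vmin < min_contrast:
        return DapiFeatures(n_blobs=0, flagged=True)
    bright = (proj > vmin + rel_threshold * (vmax - vmin)) & region
    comp = cc_label(bright, connectivity=2)
    props = [p for p in regionprops(comp) if p.area >= min_blob_px]
    if not props:
        return DapiFeatures(n_blobs=0, flagged=True)
    props.sort(key=lambda p: -p.area)
    major = props[0].axis_major_length
    minor = max(props[0].axis_minor_length, 1e-6)
    crosses = False
    if mother_link is not None:
        sub = label_mask[box]
        for p in props:
            blob = comp == p.label
            if (blob & (sub == cell_id)).any() and (blob & (sub == mother_link)).any():
                crosses = True
                break
    return DapiFeatures(
        n_blobs=len(props), elongation=float(major / minor), crosses_neck=crosses
    )


def build_records(
    label_mask: np.ndarray,
    spb_stack: np.ndarray | None = None,
    dapi_stack: np.ndarray | None = None,
    optics: OpticsConfig | None = None,
    strain_id: str = "WT",
    spb_k: float = 5.0,
) -> list[CellRecord]:
    """CellRecords for every label: geometry, bud links, SPBs, DAPI."""
    optics = optics or OpticsConfig()
    um2_per_px = (optics.pixel_size_nm / 1000.0) ** 2
    records = []
    for p in regionprops(np.asarray(label_mask)):
        records.append(
            CellRecord(
                cell_id=int(p.label),
                area_px=float(p.area),
                area_um2=float(p.area) * um2_per_px,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                strain_id=strain_id,
            )
        )
    link_buds(records, label_mask)
    for r in records:
        if spb_stack is not None:
            r.spb_count, r.spb_raw, r.spb_flagged = count_spbs(
                spb_stack, label_mask, r.cell_id, k=spb_k
            )
        if dapi_stack is not None:
            partner = r.mother_id if r.is_bud else r.bud_id
            r.dapi = dapi_features(dapi_stack, label_mask, r.cell_id, partner)
    return records


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "strain_id": r.strain_id,
                "area_px": r.area_px,
                "area_um2": r.area_um2,
                "centroid_y": r.centroid[0],
                "centroid_x": r.centroid[1],
                "is_bud": r.is_bud,
                "mother_id": r.mother_id,
                "bud_id": r.bud_id,
                "spb_count": r.spb_count,
                "spb_raw": r.spb_raw,
                "dapi_n_blobs": r.dapi.n_blobs,
                "dapi_elongation": r.dapi.elongation,
                "dapi_crosses_neck": r.dapi.crosses_neck,
                "phase": r.phase,
            }
            for r in records
        ]
    )


def size_distribution(
    areas_by_strain: Mapping[str, Sequence[float]],
    reference: str = "WT",
) -> pd.DataFrame:
    """Per-strain normalised area summaries plus Mann-Whitney tests vs WT.

    Areas are normalised to the reference strain's median (overall median
    if the reference is absent, flagged in the ``normalization`` column).
    """
    from yeastfish import exprstats

    if len(areas_by_strain) < 2:
        raise ValueError("need at least two strains")
    if reference in areas_by_strain:
        norm = float(np.median(areas_by_strain[reference]))
        norm_tag = f"median({reference})"
    else:
        norm = float(np.median(np.concatenate([np.asarray(v) for v in areas_by_strain.values()])))
        norm_tag = "overall-median (reference missing)"
    rows = []
    ref_vals = np.asarray(areas_by_strain.get(reference, []), dtype=float)
    for strain, vals in areas_by_strain.items():
        vals = np.asarray(vals, dtype=float) / norm
        summ = exprstats.letter_values(vals)
        row = {
            "strain_id": strain,
            "n": len(vals),
            "median_ratio": float(np.median(vals)),
            "mean_ratio": float(np.mean(vals)),
            "letter_values": summ,
            "normalization": norm_tag,
        }
        if strain != reference and len(ref_vals) > 0:
            res = exprstats.mw_test(vals * norm, ref_vals)
            row["mw_u"] = res.statistic
            row["mw_p"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows)
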