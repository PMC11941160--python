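"""Reading and writing rendered fields and tables.

Stacks go to multi-page TIFF (one file per channel), label masks to 16-bit
TIFF, tables to CSV, and scene/optics metadata to JSON, so a rendered
field can be consumed by external tools or re-loaded for detection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from yeastfish.optics import OpticsConfig
from yeastfish.simimages import SyntheticField


def write_field(field: SyntheticField, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for ch, stack in field.stacks.items():
        p = out / f"{ch}.tif"
        tifffile.imwrite(p, stack.astype(np.float32))
        written.append(p)
    p = out / "label_mask.tif"
    tifffile.imwrite(p, field.label_mask.astype(np.uint16))
    written.append(p)
    for name, table in (
        ("truth_counts", field.truth_counts),
        ("truth_spots", field.truth_spots),
        ("truth_objects", field.truth_objects),
    ):
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    meta = {
        "optics": {
            "pixel_size_nm": field.optics.pixel_size_nm,
            "z_step_um": field.optics.z_step_um,
            "n_z": field.optics.n_z,
            "na": field.optics.na,
            "n_immersion": field.optics.n_immersion,
            "em_wavelength_nm": dict(field.optics.em_wavelength_nm),
        },
        "channels": sorted(field.stacks),
    }
    p = out / "field.json"
    p.write_text(json.dumps(meta, indent=2))
    written.append(p)
    return written


def read_field(field_dir) -> SyntheticField:
    d = Path(field_dir)
    meta = json.loads((d / "field.json").read_text())
    optics = OpticsConfig(
        pixel_size_nm=meta["optics"]["pixel_size_nm"],
        z_step_um=meta["optics"]["z_step_um"],
        n_z=meta["optics"]["n_z"],
        na=meta["optics"]["na"],
        n_immersion=meta["optics"]["n_immersion"],
        em_wavelength_nm=meta["optics"]["em_wavelength_nm"],
    )
    stacks = {ch: tifffile.imread(d / f"{ch}.tif") for ch in meta["channels"]}
    return SyntheticField(
        stacks=stacks,
        label_mask=tifffile.imread(d / "label_mask.tif").astype(np.int32),
        truth_counts=pd.read_csv(d / "truth_counts.csv"),
        truth_spots=pd.read_csv(d / "truth_spots.csv"),
        truth_objects=pd.read_csv(d / "truth_objects.csv"),
        optics=optics,
    )


def read_outlines(path) -> dict[int, np.ndarray]:
    """Read a simple outline text file: one polygon per cell.

    Format per line: ``cell_id: y1,x1 y2,x2 ...`` (comment lines start
    with '#'); returns cell_id -> (n, 2) vertex array.
    """
    outlines = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        head, _, rest = line.partition(":")
        pts = [tuple(float(v) for v in p.split(",")) for p in rest.split()]
        outlines[int(head)] = np.asarray(pts)
    return outlines


def outlines_to_mask(outlines: dict[int, np.ndarray], shape) -> np.ndarray:
    """Rasterize outline polygons into a label mask."""
    from skimage.draw import polygon

    mask = np.zeros(shape, dtype=np.int32)
    for cid, pts in outlines.items():
        rr, cc = polygon(pts[:, 0], pts[:, 1], shape=shape)
        mask[rr, cc] = cid
    return mask
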