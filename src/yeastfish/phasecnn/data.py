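"""Labeled composite datasets from rendered synthetic fields.

Builds class-balanced training data by laying out cells with prescribed
phases (each budded unit contributes a mother and a bud object, so all
nine labels are covered), rendering the fields with the standard optics
and noise, and running the real preprocessing on every labeled object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from yeastfish.phases import BUDDED_PHASES
from yeastfish.phasecnn.model import CLASSES
from yeastfish.phasecnn.preprocess import preprocess_cell
from yeastfish.simcounts import COUNT_COLUMNS
from yeastfish.simimages import GeometryConfig, NoiseConfig, render_field, sample_scene


def _counts_for_phases(phases: list[str], seed: int, mean: float = 1.5) -> pd.DataFrame:
    """Minimal count table with prescribed unit phases (one dummy gene)."""
    rng = np.random.default_rng(seed)
    rows = []
    for cid, ph in enumerate(phases, start=1):
        total = int(rng.poisson(mean))
        base = (cid, "train", "WT", ph)
        rows.append((*base, "whole", "G", total))
        if ph in BUDDED_PHASES:
            bud = int(rng.binomial(total, 0.3))
            rows.append((*base, "mother", "G", total - bud))
            rows.append((*base, "bud", "G", bud))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def make_composites(
    n_per_class: int = 100,
    seed: int = 0,
    noise: NoiseConfig | None = None,
    units_per_field: int = 24,
    field_shape: tuple[int, int] = (440, 440),
    geometry: GeometryConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(images NHWC float32, labels int) with n_per_class of each label.

    Unit phases: ``n_per_class`` G1 units plus ``n_per_class`` units of
    each budded phase; every budded unit yields a mother and a bud
    composite, so each of the nine classes ends up with ``n_per_class``
    examples (9 * n_per_class composites total).
    """
    noise = noise or NoiseConfig()
    phases = ["G1"] * n_per_class
    for ph in BUDDED_PHASES:
        phases += [ph] * n_per_class
    rng = np.random.default_rng(seed)
    phases = list(rng.permutation(phases))

    images, labels = [], []
    for start in range(0, len(phases), units_per_field):
        chunk = phases[start : start + units_per_field]
        counts = _counts_for_phases(chunk, seed=seed + 1000 + start)
        scene = sample_scene(
            counts,
            {"G": "Cy3"},
            shape=field_shape,
            seed=seed + 2000 + start,
            geometry=geometry,
        )
        fld = render_field(
            scene,
            noise=noise,
            seed=seed + 3000 + start,
            shape=field_shape,
            fish_channels=("Cy3",),
            geometry=geometry,
        )
        partners = fld.truth_objects.set_index("label")
        bud_of_mother = {
            int(m): int(l)
            for l, m in zip(fld.truth_objects["label"], fld.truth_objects["mother_label"])
            if pd.notna(m)
        }
        for _, row in fld.truth_objects.iterrows():
            lab = int(row["label"])
            if row["role"] == "bud":
                partner = int(row["mother_label"])
            else:
                partner = bud_of_mother.get(lab)
            comp = preprocess_cell(
                {ch: fld.stacks[ch] for ch in ("BF", "SPB", "DAPI")},
                fld.label_mask,
                lab,
                partner_id=partner,
                phase=row["phase"],
            )
            images.append(comp.image)
            labels.append(CLASSES.index(row["phase"]))
    return np.stack(images), np.asarray(labels, dtype=np.int64)
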