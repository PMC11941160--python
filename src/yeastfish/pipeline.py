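"""End-to-end orchestration: simulate -> render -> detect -> classify -> stats.

A run takes one JSON-serialisable configuration, executes the stages in
order, writes every table/report plus a manifest with content hashes,
versions and seeds, and is bit-reproducible for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from yeastfish import __version__, exprstats, presets
from yeastfish.cellgeom import build_records, records_to_frame
from yeastfish.exceptions import ConfigurationError
from yeastfish.optics import OpticsConfig
from yeastfish.phaserule import classify_all
from yeastfish.simcounts import (
    calibrate_rho,
    simulate_counts,
    write_count_table,
)
from yeastfish.simimages import NoiseConfig, render_field, sample_scene
from yeastfish.spots import (
    DetectionConfig,
    assign_spots,
    counts_to_table,
    detect_spots,
    log_filter,
    spots_to_frame,
    suggest_threshold,
    _local_maxima,
)

logger = logging.getLogger("yeastfish.pipeline")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    seed: int = 0
    genes: Sequence[str] = ("CLB1", "CLB2")
    channel_map: Mapping[str, str] = dc_field(
        default_factory=lambda: {"CLB1": "Cy3", "CLB2": "Cy5"}
    )
    strains: Sequence[str] = ("WT", "clb2D")
    n_cells_counts: int = 2000
    n_cells_imaged: int = 20
    n_fields: int = 2
    field_shape: tuple[int, int] = (440, 440)
    couple_pairs: bool = True
    noise_background: float = 100.0
    noise_read_sd: float = 2.0
    detection_threshold: float | None = None  # None: automatic plateau
    compensation_d: float = 0.10
    compensation_f: float = 1.5

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "channel_map" not in raw:
            raise ConfigurationError("config is missing the channel_map section")
        raw["field_shape"] = tuple(raw.get("field_shape", (440, 440)))
        return cls(**raw)

    def validate(self) -> None:
        for g in self.genes:
            if g not in self.channel_map:
                raise ConfigurationError(f"gene {g!r} has no channel mapping")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _auto_threshold(stack, cfg: DetectionConfig) -> float:
    resp = log_filter(stack, cfg)
    vals = [resp[z, y, x] for z, y, x in _local_maxima(resp, cfg.min_separation_px)]
    return suggest_threshold(vals).threshold


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage failures abort the run with the stage name; outputs written so
    far are left in place.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "init"
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items() if not isinstance(v, Mapping)},
        "channel_map": dict(cfg.channel_map),
        "stages": [],
        "files": {},
    }
    try:
        # ---- simulate counts per strain ----------------------------------
        stage = "simulate"
        t0 = time.time()
        genes = [presets.study_gene(g) for g in cfg.genes]
        couplings = []
        if cfg.couple_pairs:
            for (a, b), target in presets.PAIR_TARGET_PEARSON.items():
                if a in cfg.genes and b in cfg.genes:
                    ga = presets.study_gene(a)
                    gb = presets.study_gene(b)
                    couplings.append(
                        calibrate_rho(target, ga, gb, n_pilot=20_000, seed=cfg.seed)
                    )
        tables = {}
        for strain_id in cfg.strains:
            strain = (
                presets.wild_type() if strain_id == "WT" else presets.deletion_strain(strain_id)
            )
            tables[strain_id] = simulate_counts(
                genes, couplings, strain, n_cells=cfg.n_cells_counts, seed=cfg.seed
            )
            write_count_table(tables[strain_id], out / f"counts_sim_{strain_id}.csv")
        manifest["stages"].append({"name": stage, "seconds": time.time() - t0})

        # ---- render fields and detect spots (WT) -------------------------
        stage = "render+detect"
        t0 = time.time()
        noise = NoiseConfig(background=cfg.noise_background, read_noise_sd=cfg.noise_read_sd)
        optics = OpticsConfig()
        all_measured = []
        all_spots = []
        records_frames = []
        wt_table = tables[cfg.strains[0]]
        whole = wt_table[wt_table.compartment == "whole"]
        cells_per_field = cfg.n_cells_imaged
        for f_idx in range(cfg.n_fields):
            lo = f_idx * cells_per_field
            cell_ids = whole.cell_id.unique()[lo : lo + cells_per_field]
            sub = wt_table[wt_table.cell_id.isin(cell_ids)]
            if sub.empty:
                break
            scene = sample_scene(
                sub, cfg.channel_map, shape=cfg.field_shape,
                optics=optics, seed=cfg.seed + 10 + f_idx,
            )
            fld = render_field(
                scene, optics=optics, noise=noise, seed=cfg.seed + 50 + f_idx,
                shape=cfg.field_shape,
                fish_channels=tuple(sorted({cfg.channel_map[g] for g in cfg.genes})),
                channel_map=cfg.channel_map,
                strain_id=cfg.strains[0], experiment_id=f"field{f_idx}",
            )
            assignments = {}
            for ch in sorted({cfg.channel_map[g] for g in cfg.genes}):
                det_cfg = DetectionConfig(channel=ch, threshold=0.0, optics=optics)
                thr = (
                    cfg.detection_threshold
                    if cfg.detection_threshold is not None
                    else _auto_threshold(fld.stacks[ch], det_cfg)
                )
                det_cfg = DetectionConfig(channel=ch, threshold=thr, optics=optics)
                spots = detect_spots(fld.stacks[ch], det_cfg)
                counts, assigned = assign_spots(spots, fld.label_mask)
                assignments[ch] = counts
                sf = spots_to_frame(assigned)
                sf["field"] = f_idx
                all_spots.append(sf)
            # cell features + rule phases
            records = build_records(
                fld.label_mask, fld.stacks["SPB"], fld.stacks["DAPI"], optics,
                strain_id=cfg.strains[0],
            )
            classify_all(records)
            rec_frame = records_to_frame(records)
            rec_frame["field"] = f_idx
            records_frames.append(rec_frame)
            bud_links = {r.cell_id: r.mother_id for r in records if r.is_bud}
            phases = {r.cell_id: (r.phase or "unassigned") for r in records}
            gene_per_channel = {ch: g for g, ch in cfg.channel_map.items()}
            measured = counts_to_table(
                assignments, gene_per_channel,
                strain_id=cfg.strains[0], experiment_id=f"field{f_idx}",
                phases=phases, bud_links=bud_links,
            )
            measured["field"] = f_idx
            all_measured.append(measured)
        measured_table = pd.concat(all_measured, ignore_index=True)
        measured_table.to_csv(out / "counts_measured.csv", index=False)
        pd.concat(all_spots, ignore_index=True).to_csv(out / "spots.csv", index=False)
        pd.concat(records_frames, ignore_index=True).to_csv(
            out / "cell_records.csv", index=False
        )
        manifest["stages"].append({"name": stage, "seconds": time.time() - t0})

        # ---- statistics ---------------------------------------------------
        stage = "stats"
        t0 = time.time()
        report: dict = {"summaries": {}, "pearson": {}, "compensation": {}}
        wt = tables[cfg.strains[0]]
        for g in cfg.genes:
            counts = wt[(wt.gene_id == g) & (wt.compartment == "whole")]["count"]
            s = exprstats.summarize(counts.to_numpy(), gene=g, strain=cfg.strains[0])
            report["summaries"][g] = {
                "n_cells": s.n_cells,
                "mean": s.mean,
                "zero_fraction": s.zero_fraction,
                "max": s.max_count,
            }
        for (a, b) in presets.PAIR_TARGET_PEARSON:
            if a in cfg.genes and b in cfg.genes:
                piv = whole.pivot(index="cell_id", columns="gene_id", values="count")
                res = exprstats.pearson_pair(piv[a], piv[b])
                report["pearson"][f"{a}/{b}"] = {"r": res.statistic, "p": res.p_value}
        for strain_id in cfg.strains[1:]:
            deleted = presets.DELETED_GENE.get(strain_id)
            if deleted is None:
                continue
            surviving = [
                g for pair in presets.PAIR_TARGET_PEARSON
                if deleted in pair for g in pair if g != deleted and g in cfg.genes
            ]
            for g in surviving:
                rep = exprstats.compensation_report(
                    tables[cfg.strains[0]], tables[strain_id], g,
                    paralogue_deleted=deleted,
                    d=cfg.compensation_d, f=cfg.compensation_f,
                )
                report["compensation"][f"{g}_in_{strain_id}"] = {
                    "delta_zero_fraction": rep.delta_zero_fraction,
                    "mean_fold_change": rep.mean_fold_change,
                    "p_overall": rep.overall_test.p_value,
                    "verdict": rep.verdict,
                }
        (out / "stats_report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"].append({"name": stage, "seconds": time.time() - t0})
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = _sha256(p)
    manifest["total_seconds"] = time.time() - t_start
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.1fs", manifest["total_seconds"])
    return out


def make_fixtures(size: str = "tiny", seed: int = 0, out_dir=None):
    """Bundled synthetic dataset: 'tiny' (1 field, ~10 cells) or 'demo'
    (10 fields, ~300 cells, all 9 phases, WT + clb1D/clb2D analogues)."""
    from yeastfish.io import write_field

    if size == "tiny":
        n_fields, cells_per_field, strains = 1, 10, ["WT"]
    elif size == "demo":
        n_fields, cells_per_field, strains = 10, 30, ["WT", "clb1D", "clb2D"]
    else:
        raise ValueError("size must be 'tiny' or 'demo'")
    genes = [presets.study_gene(g) for g in ("CLB1", "CLB2")]
    channel_map = {"CLB1": "Cy3", "CLB2": "Cy5"}
    fields = []
    for i in range(n_fields):
        strain_id = strains[i % len(strains)]
        strain = (
            presets.wild_type() if strain_id == "WT" else presets.deletion_strain(strain_id)
        )
        table = simulate_counts(
            genes, strain=strain, n_cells=cells_per_field,
            seed=seed + i, experiment_id=f"fixture{i}",
        )
        scene = sample_scene(table, channel_map, shape=(470, 470), seed=seed + 100 + i)
        fld = render_field(
            scene, seed=seed + 200 + i, shape=(470, 470),
            fish_channels=("Cy3", "Cy5"), channel_map=channel_map,
            strain_id=strain_id, experiment_id=f"fixture{i}",
        )
        fields.append(fld)
        if out_dir is not None:
            write_field(fld, Path(out_dir) / f"field_{i:02d}_{strain_id}")
    return fields
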