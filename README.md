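# yeastfish

Simulation and quantification of single-molecule FISH (smFISH) mRNA counts
in budding yeast, built around the question of how *paralogous* cell-cycle
genes — CLN1/CLN2, CLB1/CLB2, CLB3/CLB4, CLB5/CLB6, SWI5/ACE2 — differ in
expression strength, timing, localization and mutual genetic compensation.

It is aimed at people who analyze (or plan) smFISH experiments in yeast:
the package renders realistic multi-channel z-stacks with complete ground
truth, detects and counts diffraction-limited mRNA spots per cell,
classifies cells into nine cell-cycle phase labels (a deterministic
spindle-pole-body rule and an attention CNN), and computes the statistics
that such studies report.

## What is inside

**Count simulator** (`simcounts`). Per-cell transcript counts follow a
compound Poisson–geometric ("bursty") model: a cell in phase *p* draws
`N ~ Poisson(mu_p / s)` bursts of geometric size with mean `s = (b+1)/2`,
giving mean `mu_p` and Fano factor exactly `b`; `b = 1` is Poisson
(constitutive). Paralogue co-expression is a Gaussian copula applied to
the exact compound-count quantiles, so marginals are preserved and
`calibrate_rho` can invert the copula attenuation to hit a target
count-level Pearson correlation. Deletion strains zero out a gene and
scale the partner's mean (compensation); transcripts of budded cells are
allocated to the bud with a gene-specific probability (She2p-dependent
transport for CLB2).

**Image simulator** (`simimages`). Widefield optics (100×/NA 1.4, 130 nm
pixels, 32 z-planes at 0.25 µm); spots are 3-D Gaussians with
`sigma_xy = 0.21 λ/NA`, `sigma_z = 0.66 λ n/NA²`; nuclei, spindle pole
bodies, brightfield rims and camera noise (Poisson + read) complete the
field. Every rendered object is recorded in truth tables.

**Spot detection** (`spots`). Scale-normalised Laplacian-of-Gaussian
filtering at the channel's PSF width, 3-D local maxima, least-squares 3-D
Gaussian refinement, automatic threshold suggestion from the plateau of
the count-versus-threshold curve, and 2-D mask assignment.

**Phase classification** (`cellgeom`, `phaserule`, `phasecnn`). Cell
records carry area, SPB count (local thresholding of the marker channel),
bud–mother links and DAPI morphology; a decision list maps these to G1 /
S / G2 / Early-M / Late-M (+ bud mirrors). The CNN takes 80×80×3
composites (brightfield, SPB, DAPI; std-projected over z, cell boundary
overlaid), runs five conv blocks (32→512 filters) with channel+spatial
attention, and trains with class-balanced batches and focal loss — all
implemented on numpy + numba, no deep-learning framework required.
Predictions can be confidence-filtered per class (drop the lowest 20%).

**Statistics** (`exprstats`, `growth`, `seqident`). Letter-value
summaries (boxenplot ladders), Pearson co-expression, Mann–Whitney U
(exact by enumeration for small untied samples), phase-resolved
expression, mother/bud enrichment, compensation reports
(Δ zero-fraction + mean fold change), OD600 doubling times
(`T = ln 2 / rate` over the automatically chosen exponential window), and
local-alignment percent identity (BLOSUM62, BLAST-default gaps).

## Worked example

```python
import numpy as np
from yeastfish import presets
from yeastfish.simcounts import calibrate_rho, simulate_counts, apply_compensation_scenario
from yeastfish.exprstats import compensation_report, pearson_pair, summarize

genes = [presets.study_gene("CLB1"), presets.study_gene("CLB2")]
coupling = calibrate_rho(0.51, genes[0], genes[1], n_pilot=20_000, seed=1)
wt = simulate_counts(genes, [coupling], strain=presets.wild_type(), n_cells=5000, seed=1)
deletion = apply_compensation_scenario(wt, presets.deletion_strain("clb2D"))

whole = wt[wt.compartment == "whole"]
for g in ("CLB1", "CLB2"):
    s = summarize(whole.loc[whole.gene_id == g, "count"].to_numpy(), gene=g, strain="WT")
    print(f"{g}: mean {s.mean:.2f} spots/cell, {100*s.zero_fraction:.0f}% of cells empty, max {s.max_count:.0f}")
piv = whole.pivot(index="cell_id", columns="gene_id", values="count")
r = pearson_pair(piv["CLB1"], piv["CLB2"])
print(f"CLB1/CLB2 Pearson r = {r.statistic:.2f} (p = {r.p_value:.1e})")
rep = compensation_report(wt, deletion, "CLB1", "CLB2")
print(f"CLB1 in clb2D: zero fraction {rep.delta_zero_fraction:+.2f}, "
      f"mean fold change {rep.mean_fold_change:.2f}, compensation: {rep.verdict}")
```

prints

```
CLB1: mean 0.83 spots/cell, 67% of cells empty, max 13
CLB2: mean 0.71 spots/cell, 62% of cells empty, max 10
CLB1/CLB2 Pearson r = 0.50 (p = 3.8e-313)
CLB1 in clb2D: zero fraction -0.33, mean fold change 4.64, compensation: True
```

Read: wild-type CLB1 averages 0.83 transcripts per cell with two thirds of
cells empty (bursty, low expression); the calibrated generator reproduces
the target co-expression (r ≈ 0.51); deleting CLB2 raises CLB1 roughly
4.7-fold and fills in the zero class — the signature the compensation
verdict tests for.

A command-line interface mirrors the pipeline
(`yeastfish simulate / make-fixtures / detect / cells / classify-rule /
cnn-train / cnn-predict / stats / growth / seqid / run`); `yeastfish run
--config cfg.json` executes simulate → render → detect → classify → stats
and writes a manifest with content hashes so runs are reproducible.

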