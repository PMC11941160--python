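# Methods

This note documents the models behind `yeastfish`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions that matter for reproducing results.

## Per-cell count model

A gene is described by a mean `mu_p` of transcripts per cell in each
cell-cycle phase *p* and a dispersion `burst_size` `b >= 1`.  Counts are
compound Poisson–geometric: `N ~ Poisson(mu_p / s)` transcriptional bursts
of geometric size (support >= 1) with mean `s = (b + 1) / 2`, summed.
This is the telegraph-model limit commonly used for bursty expression.
The parametrization is chosen so that `b` **is the Fano factor** of the
counts (for geometric burst sizes of mean `s` the Fano factor is
`2s − 1`); `b = 1` collapses to a Poisson distribution, which is also
what `mode="constitutive"` produces, so the constitutive/bursty continuum
is a single dial.

Zero fractions follow in closed form: `P(0 | p) = exp(−mu_p / s)`, and the
population zero fraction is the phase-occupancy average.  This is what
the preset calibration inverts (below).

**Paralogue coupling.** Co-expression is modelled by a Gaussian copula: a
pair shares a latent bivariate normal with correlation `rho_latent`, and
each gene maps its uniformized latent through the *exact* quantile
function of its compound count distribution (CDF computed by Panjer
recursion per distinct phase mean).  Applying the copula to total counts
(rather than to an intermediate stage such as the burst number) preserves
every marginal exactly and makes the attainable count-level correlation
range as wide as the Fréchet bound allows — important because the strongly
coupled pairs (count Pearson ≈ 0.68 for the G1 cyclin pair) are otherwise
unreachable once burst-size noise is left uncoupled.

Discreteness and zero inflation still attenuate the count correlation
below `rho_latent`.  `calibrate_rho` inverts this numerically: the count
Pearson at fixed common random numbers is nondecreasing in `rho_latent`,
so a bisection against pilot simulations (default 50 000 cells) finds the
latent value that reproduces a target, and reports the maximum attainable
correlation when a target exceeds the comonotone bound (possible for very
dissimilar marginals).

**Phase occupancy.**  The nine object-level labels are G1, S, G2,
Early-M, Late-M plus the four `*-Bud` mirrors.  A *sampling unit* is a
whole cell: G1 units are unbudded; S/G2/Early-M/Late-M units carry a bud,
which becomes a second segmented object with the `-Bud` label.  The
default occupancy (G1 0.30, S 0.08, G2 0.14, Early-M 0.07, Late-M 0.07,
and bud entries 0.08/0.14/0.06/0.06) deliberately overrepresents G1 and
underrepresents S, the assignment bias expected for asynchronous cultures
segmented from projected images (small buds are frequently missed, and
1-SPB budded cells are ambiguous).  Unit phases use the renormalised
mother-side entries.

**Strains.**  A deletion sets a gene's counts to zero (rows are still
emitted — explicit zeros matter for zero-fraction statistics);
`compensation_factor` multiplies the partner's phase means before
sampling; deletion tables are *re-simulated* (independent draws under a
different seed stream), not transformed from the wild-type table, because
real comparisons are between independently grown cultures.  Transcripts
of budded cells go to the bud independently with a per-gene probability
(`bud_transport`); `she2_active=False` caps that probability at a passive
0.10, emulating loss of She2p-dependent transport with residual
diffusion.

**Seed policy.**  One root seed; child streams are derived
deterministically from (seed, strain, experiment) via CRC32 keys, so a
wild-type/deletion pair under one root seed is reproducible yet mutually
independent.

## Gene presets

`presets.study_gene` encodes the eleven genes of the paralogue panel.
Overall means and wild-type zero fractions follow reported smFISH
measurements where available (e.g. the G1 cyclins at 1.68 and 1.89
spots/cell; the first B-type cyclin pair at 0.8/0.7 spots per cell with
68%/62% empty cells); the remaining values, and all relative phase
shapes, are this package's calibration, shaped to the canonical timing
(G1 cyclins late G1–S, S-phase cyclins G1/S, the CLB3/CLB4 pair S–G2, the
mitotic pair peaking in G2, the exit transcription factors G2–M).  Phase
shapes are rescaled so the occupancy-weighted mean is exact, and
`burst_size` is solved by bisection so the occupancy-weighted zero
fraction matches its target (clamped at the Poisson limit when the target
lies below it — sub-Poisson zero fractions are unreachable in this model
family).  mRNA half-lives are attached as metadata only; no decay
dynamics are simulated.

Compensation factors for the deletion presets use the two pairs with
printed means (fold 4.75 and ≈1.86) and qualitative calibration for the
rest (clear compensation for the CLB3/CLB4 pair and CLN1, none for the
S-phase pair, CLN2 and SWI5).  Bud transport defaults: 0.55 for the
bud-localized mitotic cyclin, 0.15 for its mother-retained paralogue,
0.25 for unlisted genes.

## Image simulator

Optics defaults describe the assumed acquisition: 100×/NA 1.4 oil
objective, 130 nm sample-side pixels (13 µm camera pixels / 100×; the
camera pixel pitch is the package's assumption), 32 z-planes at 0.25 µm,
emission maxima 576/664/523/474/461 nm for Cy3/Cy5/YFP/SPB/DAPI.  Spots
render as 3-D Gaussians with the standard widefield approximation
`sigma_xy = 0.21 λ/NA`, `sigma_z = 0.66 λ n/NA²` (0.665 px and 1.18
z-planes for Cy3), truncated at 4σ (truncation error < 0.1% of the spot
energy; an integral test holds to 2%).

Cells are ellipses (semi-axes 11–15 px ≈ 3–4 µm diameter) on a jittered
grid; budded phases attach a bud ellipse of phase-dependent area ratio
(S 0.12 → Late-M 0.45, all below the 0.5 linking threshold) tangent to
the mother with a ~1 px gap, so masks never overlap yet always pass the
2-px-dilation adjacency test.  SPB counts per phase: one in G1/S and both
M stages, two only in G2, none in buds.  Nuclei are DAPI Gaussian blobs:
round (G1/S/G2), a chain stretched from mother center into the bud
(Early-M), or two separated blobs (Late-M).  The brightfield channel is a
schematic rim along mask boundaries with a focal z-profile — sufficient
as CNN input, not an optical simulation.

Spot amplitude defaults to 150 counts (±20% per-spot jitter) over a
background of 100 with Poisson shot noise and 2-count read noise, i.e.
peak SNR ≈ 15 — bright, well-sampled smFISH conditions.  Spots of one
cell and channel are kept ≥ 4 px apart laterally (or ≥ 5 z-planes axially)
during placement: co-located emitters are physically unresolvable and
would make "recover every truth spot" an impossible target for any
detector, which would test the simulator rather than the detection.

**Not emulated** (and therefore not probed by passing tests):
segmentation errors (masks are exact), unsegmented small buds, cell
overlap and crowding, spherical aberration and depth-dependent PSFs,
photobleaching, autofluorescence, transcription-site aggregates, and
cell-size-coupled expression.  Real-data performance will be worse than
synthetic-field performance wherever those effects matter.

## Spot detection

Scale-normalised LoG (response multiplied by `sigma_xy²`, so thresholds
are comparable across channels), 3-D local maxima with a minimum lateral
separation (default 2 px), and least-squares 3-D Gaussian refinement in a
7×7×5 window initialised at the PSF width.  Fit failures keep the integer
maximum and are flagged `refined=False`.  Coordinates are 0-based
`(z, y, x)` with voxel centers at integers.

`suggest_threshold` automates the manual threshold choice: the spot count
as a function of threshold is a step function dropping at each candidate
response; the widest gap between consecutive sorted responses is the
longest stable plateau and, with clear signal/background separation, sits
between the noise and spot modes (the midpoint is returned).  If the
widest gap is < 5× the median gap the curve is considered plateau-free
and the knee (maximum distance from the chord) is returned flagged
low-confidence.

Assignment is 2-D: the label under the rounded `(y, x)`; border spots go
to whichever label owns that pixel, without splitting.  Zero-count cells
are emitted explicitly in count tables.

## Cell features and the phase rule

SPB counting thresholds the z-max projection of the marker crop at local
mean + 5 sd and counts connected components overlapping the cell's own
pixels; counts above two are capped and flagged.  Bud linking marks a
cell as a bud when its area is below 0.5× a neighbor's and the masks
touch within 2 px dilation; the largest admissible neighbor wins, ties
broken by shared boundary length.  DAPI features threshold the z-max
projection at `vmin + 0.3 (vmax − vmin)` inside the mother∪bud footprint
dilated by 3 px — the dilation bridges the unlabeled neck gap so a
stretched anaphase nucleus is one blob that `crosses_neck`, not two.

The rule decision list (first match wins): bud → mother's phase + "-Bud";
unbudded, 1 SPB, single compact nucleus → G1; budded, 1 SPB, compact
nucleus confined to the mother → S; budded, 2 SPB, compact nucleus → G2;
budded, nucleus crossing the neck → Early-M; budded, divided nucleus →
Late-M; anything else → unassigned.  The S rule requires the compact
nucleus explicitly because Early/Late-M mothers also carry one SPB — an
unconditioned "budded + 1 SPB → S" would shadow the mitosis rules.
Conflicts (e.g. unbudded with two SPBs) are left unassigned rather than
guessed so downstream statistics can exclude them.  On noiseless rendered
fields the rule is exact by construction; that verifies the geometry →
features → rule chain, not robustness to real imaging.

## The attention CNN

Input composites are 80×80×3 (brightfield, SPB, DAPI): crop of the cell
plus its linked partner with a 4 px margin, per-channel standard-deviation
projection along z, local thresholding of the SPB plane (mean + 5 sd),
the *cell's own* boundary overlaid at the channel maximum (this is what
distinguishes a bud's composite from its mother's — the two share the
frame), square-padding or isotropic downscaling to 80 px, and per-channel
min–max normalisation.

Architecture: five blocks of convolution (3×3) → batch norm → channel
attention → spatial attention → ReLU → 2×2 max pool, filters
32→64→128→256→512 (spatial 80→40→20→10→5→2), then one fully connected
block (2048→256, ReLU, dropout 0.5) and a 9-way output.  Attention
follows the CBAM design: channel attention first (average- and max-pooled
descriptors through a shared 2-layer MLP, reduction 8), then spatial
attention (channel-wise mean and max maps through a 7×7 convolution),
both sigmoid-gated.  Unspecified hyperparameters default to kernel 3×3,
fc 256, dropout 0.5, Adam at 1e-3, focal loss with α=1, γ=2, batch 64 —
all configurable.

Training draws class-balanced batches (classes uniform with replacement),
applies on-the-fly augmentation — right-angle rotations, horizontal and
vertical flips, per-channel gain jitter ±20% (the single-intensity-channel
analogue of saturation jitter) and contrast jitter ±20% — and minimises
focal loss `FL = −α (1−p_t)^γ log p_t`.  An epoch is `ceil(n / batch)`
batches.  "Confidence" is the softmax probability of the predicted class;
per-class filtering drops the `floor(0.2 · n_class)` least confident
cells of each *predicted* class, ties broken by cell id.  Evaluation uses
stratified 5-fold cross-validation with accuracy, macro F1, one-vs-all
AUC and the confusion matrix, before and after filtering.

The network is implemented directly on numpy (BLAS GEMMs via im2col) with
fused numba kernels for the memory-bound passes; activations are
channel-major float32.  Every max (pooling, attention poolings) breaks
ties toward the first maximum, and all randomness (init, batches,
augmentation, dropout) flows from the config seed, so runs are
bit-reproducible.  Augmentation-group invariance of predictions is *not*
claimed — augmentation is a train-time regulariser only.

Synthetic training data (`make_composites`) renders class-balanced fields
with the standard optics/noise and prescribed unit phases, then runs the
real preprocessing on every labeled object.  These are "easy" in the
sense that phases are geometrically unambiguous and segmentation is
exact; accuracies on them (≈0.85–0.93 validation at 100/class and 10
epochs in our runs) bound real-data performance from above.  Confidence
filtering raised accuracy in every run, consistent with its purpose.

## Statistics

Letter values use the classic depth recursion `d_1 = (1+n)/2`,
`d_{k+1} = (1 + floor(d_k))/2`, values averaged between the bracketing
order statistics from each end; the ladder stops before a letter whose
depth floor falls below 8 observations (thinner letter classes are tail
noise).  A quantile oracle at the same depths verifies the recursion.

Pearson correlation and its t-based p-value come from `scipy`; zero
variance raises rather than returning NaN.  The Mann–Whitney U statistic
is the first sample's U from midranks; with `n1+n2 <= 12` and no ties the
p-value is exact (the U distribution built by the standard counting
recursion, validated against full enumeration), otherwise a normal
approximation with tie correction and continuity correction (validated
against an independent implementation and by simulated null rejection
rates of ≈5% at α=0.05).  Tests are two-sided by default; no
multiple-testing correction is applied by default (effect magnitudes are
the object of interest at these sample sizes), with Benjamini–Hochberg
available.

The compensation verdict requires the zero fraction to drop by more than
`d = 0.10` *and* the mean to rise by more than `f = 1.5` — both
configurable, chosen so that the clearly compensating scenarios pass and
a pure deletion without upregulation does not.  Bud enrichment reports
`bud/(mother+bud)` per budded cell (pairs with zero total excluded) and a
Wilcoxon signed-rank test against 0.5.

## Growth curves

`rate` is the slope of log(OD) over the exponential window — the longest
contiguous span whose log-linear fit has R² ≥ 0.99 (flat segments are
excluded by construction: zero-variance spans never qualify), ties broken
by R².  `doubling_time = ln 2 / rate`; rates at numerical-noise level
(≤ 1e-9 / h) are flagged non-growing with infinite doubling time.  The
window may include the first saturating point of a sharply kinked curve,
biasing the rate a few percent low — visible in the tests and accepted as
the cost of a parameter-free window rule.

## Sequence identity

Local (Smith–Waterman) alignment via Biopython's `PairwiseAligner` with
BLAST-style scoring: BLOSUM62 with gap open 11 / extend 1 for proteins
(a length-L gap costs 11 + L, i.e. open −12 / extend −1 in aligner
convention) and +2/−3 with gap 5/2 for DNA.  Percent identity is
identities over alignment columns (gap columns included) of the best
local alignment.  Exact agreement with BLAST's traceback is not claimed;
a ±2-point band is the appropriate comparison tolerance.  A fetch helper
can retrieve sequences by systematic yeast gene name from NCBI; it
requires network access and is never called implicitly.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: 20 000 cells
for moment checks, 5 000 cells per pair for correlation recovery
(pilot 20 000), ten 400×400 fields (~200 cells) for detection recovery,
~300 objects for the rule classifier, 2 000 simulations for the
Mann–Whitney null, and one to three CNN trainings of 10 epochs on 900
composites (100 per class, 720/180 train/validation split).  These sizes
make every stochastic criterion's sampling error small against its
tolerance while keeping a full run in the minutes range on one CPU.

## Known limitations

- The generator couples paralogue *pairs*; arbitrary coupling graphs are
  accepted but must form a positive-definite latent correlation matrix.
- Zero fractions below the Poisson limit are unreachable (no
  sub-Poisson/zero-deflated mode).
- Detection assumes isolated diffraction-limited emitters; no dense-spot
  deconvolution or transcription-site decomposition.
- The 2-D mask convention means z is ignored for cell assignment.
- The CNN is trained and validated on synthetic composites only; no claim
  is made about annotated real-image accuracy.
- The growth model fits a single exponential window; no lag/stationary
  (logistic) modelling.
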