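# Methods

## The assay being modelled

A stable S2R+ cell line expresses GFP-tagged mutant VAP(P58S) under an
inducible promoter.  Induced cells form bright intracellular inclusions
(puncta); uninduced or wild-type-like cells show only diffuse reticular
GFP.  The screen images two channels per field (nuclei and GFP) in a
384-well plate: each gene knockdown occupies three randomly placed wells,
42 wells carry negative controls, ten fields are imaged per well with ~400
cells per field, so one gene is represented by ~12,000 cells.  The
companion in-vivo assay images 3D confocal stacks of larval brains and
counts bright aggregates per um^3 of ventral nerve cord.

## Synthetic data generator

The generator is first-class code: it defines the study conditions on which
every calibration claim is made.

**Fields.**  Cells sit on a jittered grid with spacing three times the
nucleus radius; this guarantees non-overlap, gives an exact capacity bound
(`LayoutError` when `n_cells` exceeds it), and leaves enough irregularity
for the watershed and size filters to matter.  Nuclei are Gaussian-profile
ellipses (axis ratio up to 1.5, amplitude jittered 0.8-1.2x) so the
contrast-stretch + threshold stage is nontrivial.  Each aggregate-positive
cell carries 1-3 puncta (Poisson with mean 1.2, truncated to {1,2,3})
rendered as near-plateau disks of diameter 4-7 px placed within 0.4 cell
radii of the nucleus centre (inclusions are perinuclear); the flat profile
keeps a single punctum's thresholded footprint (13-38 px) above the
macro's 10 px particle floor, so every true aggregate is detectable in
principle.  All cells receive a diffuse Gaussian footprint of the cell
radius (the reticular signal); both channels are multiplied by a random
low-order polynomial illumination surface (default amplitude 0.15 of the
mean) and carry additive Gaussian noise (default sd 2 AFU against a
nucleus amplitude of 120 and punctum amplitude of 150).

Positivity is assigned by thresholding one uniform draw per cell, so the
positive sets are monotone-coupled across `positive_fraction` values at a
fixed seed, and the number of positive cells per field is Binomial(n, p) —
the sampling noise a fraction measured over ~400 cells actually has.

Default conditions: `n_cells=400`, `image_shape=(640, 640)`,
`positive_fraction=0.85` (the mutant-like state at 500 uM / 24 h);
`FieldSpec.wild_type_like()` uses fraction 0.05 with a stronger diffuse
signal.  The dose/time model is linear with clipping to [0, 1]:
`f = 0.10 + 3e-4 * conc_uM + 0.025 * hours`, chosen so that the screen
condition (500 uM, 24 h) gives 0.85 and the 100-700 uM range at 24 h stays
in the unclipped linear regime used by the slope-recovery test.

**Plate-scale simulations.**  Rendering 400 nuclei of radius 10 px requires
a 640 px field; simulating all 384 wells x 10 such fields is needlessly
expensive for calibration questions that only depend on per-well cell
counts.  Plate-level runs therefore use a desk-scale field — 60 cells in
256 x 256 px, 3 fields per well (~180 cells per well) — which preserves the
statistical structure (binomial positivity, per-field illumination and
noise) at ~1/20 of the pixels.  Field-level claims (the mutant/wild-type
detection contrast) always use the full 400-cell condition.

**Brain stacks.**  Puncta are solid digital balls whose radius is found by
bisection on the rendered voxel count, so a requested size always lands
inside the detectable 10-1000 voxel range; centres are placed without
overlap, optionally with a fixed fraction inside the three ROI boxes.
Truth records every centre and the per-ROI counts.

## Screen analysis pipeline

**Preprocessing.**  Illumination correction divides the nuclei channel by
an intensity-weighted least-squares quadratic surface (floored at 5% of its
maximum to keep the division stable), then rescales min-max to [0, 1] (a
constant image maps to 0.5).  A windowed Gaussian-smoothing estimate was
measured and rejected: it is boundary-biased (the illumination is
underestimated wherever cell density drops near the field edge) and left a
~15% residual gradient where the global polynomial fit leaves under 5%;
weighting the fit by intensity makes it track the gradient on the bright
structures that carry it rather than sagging toward the empty background.
Nuclei are Otsu-thresholded, filtered by a two-sided area cutoff (default
20-2000 px) and labelled with 8-connectivity.  ROIs are lattice disks of
the cellular radius (10 px) around each nucleus centroid rounded to the
nearest pixel — the centroid pixel is what gets dilated, which also makes
the 317-px area at radius 10 exact; contested pixels go to the nearest
centroid with ties to the lower label, keeping ROIs disjoint so per-cell
totals stay additive.
Nuclei with solidity < 0.8 (clumps) or ROI intensity variance below a
configurable floor (out-of-focus; disabled by default since the generator
does not model defocus) contribute no ROI.

**Features.**  The GFP channel is background-corrected by a top-hat:
`gfp - opening(gfp, disk(3))`, floored at 0.  The opening removes compact
bright puncta and keeps the smooth background, so the difference retains
puncta and is invariant to any constant pedestal.  Per cell, the average
and total corrected intensity over the ROI are recorded.

**Macro-equivalent counters** (the route used for dose-response curves):
cell counts come from 8-bit conversion (linear min-max), subtraction of the
image mean floored at 0, Otsu binarisation, distance-transform watershed
and a particle filter of 10-500 px with circularity in [0, 1] (the recorded
macro's "circularity 1" is read as no exclusion — a strict equality filter
would reject nearly every discrete particle).  Aggregate-positive counts
come from a top-hat whose disk radius interprets the macro's recorded
rolling-ball radius 0.3 as a fraction of the cell diameter (0.3 x 20 px =
6 px), because a sub-pixel morphological background estimate is degenerate
(it would erase the image); the 6 px disk removes the diffuse reticular
footprint (diameter ~20 px) while passing puncta (diameter <= 7 px).
Binarisation uses Otsu with a robust floor (median + 6 x 1.4826 x MAD of
the top-hat image) so pure-noise fields yield zero objects; a morphological
closing of radius 5 px (half the cell radius) integrates puncta of one
cell into a single object; objects of 10-500 px are counted.

**Hit calling.**  For each well and intensity parameter the signed
two-sample KS statistic against the pooled plate controls is computed in
O((n+m) log nm) via the D+/D- decomposition; positive sign means the
well's intensities are stochastically smaller (suppressor direction).
Control wells get leave-one-out statistics; their median and scaled MAD
(1.4826 x MAD) define the plate null, and `z = (D - median) / scale`.
Robust location/scale, not mean/SD, so a few contaminated control wells
cannot inflate the null.

The decision threshold is calibrated for the exact 2-of-3 rule by Monte
Carlo: each pseudo-gene draws three distinct control wells and bootstraps
each well's cell set (resampling cells with replacement) before recomputing
its KS statistic and z-score; the pseudo-gene is scored by its
second-largest |z| and the threshold is the (1 - alpha) quantile (default
alpha 0.001, 10,000 simulations, "higher" interpolation).  The cell-level
bootstrap matters: resampling only the 42 precomputed control z-values caps
the simulated null at the observed control extremes and was measurably
anti-conservative (several false-positive genes per plate on some null
plates); with the bootstrap the null tail is estimated beyond the observed
values and the calibration errs slightly conservative — consistent with a
screen design that reported zero false positives alongside 25-38% false
negatives.  A gene is a hit iff at least 2 of its 3 replicate |z| exceed
the threshold; direction is annotated from the signs of the qualifying
replicates.

**Error rates and categories.**  Against simulation truth, the
false-positive rate is called-hit nulls over nulls and the false-negative
rate is missed modifiers over modifiers.  Category summaries report
100 x hits-in-category / screened-in-category for an externally supplied
gene-to-category table.

## Brain density pipeline

Voxels above threshold (default: the 99.5th intensity percentile of the
stack, standing in as a reproducible rule for the assay's per-image manual
threshold; an absolute override is available) are grouped with
26-connectivity; components outside the inclusive 10-1000 voxel range are
discarded (the assay text excludes objects "greater than 1000" and
"smaller than 10", making the bounds inclusive).  Objects belong to an ROI
iff their centroid lies in the half-open box [lo, hi).  Per animal, the
density is the mean per-ROI count divided by the (congruent) ROI volume in
um^3.  Densities are normalised to the control-group mean (control mean
exactly 1 by construction).  Two groups are compared by a two-sided
Student's t-test; multiple groups by one-way ANOVA followed by Fisher's
LSD — unadjusted pairwise t-tests on the pooled within-group variance with
N - k degrees of freedom.  LSD p-values are reported unadjusted by
definition; the output labels them as such.

## Determinism and numerics

All randomness flows from integer seeds through named `SeedSequence`
substreams (layout, fields, screen wells, Monte Carlo), so identical
(inputs, seed) give bit-identical images, truth tables and output files;
TSV/JSON outputs use fixed float formatting to keep reruns byte-identical.
Degenerate inputs have defined behaviour: all-zero images pass through
preprocessing unchanged, empty foregrounds give zero nuclei, a degenerate
null (zero MAD) and a fraction with zero cells raise explicit errors, and
a detection threshold above the stack maximum yields zero objects.

## What passing tests do and do not show

The generator reproduces the statistical structure the pipelines assume —
binomial positive counts, smooth multiplicative illumination, compact
bright puncta over diffuse signal, non-overlapping nuclei — but not
photorealistic optics: no PSF, no defocus, no cell clumping or motion, no
autofluorescence texture.  Exact-count results (segmentation recovering
every nucleus, 3D detection recovering every punctum on noise-free stacks)
certify the pipeline's bookkeeping, not its robustness to real microscope
artefacts.  Calibration results (null plates calling zero hits, planted
suppressors recovered with zero false positives) show the statistic and
its Monte-Carlo threshold are correctly calibrated under the modelled
noise; on real data the control wells would additionally carry edge and
batch effects that the robust (median/MAD) normalisation is designed to
absorb but that are not simulated here.  The screen's published
false-negative rates cannot be targeted because the original threshold's
alpha is unknown and the raw images are not deposited.
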