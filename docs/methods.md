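# Methods

This note records the models, conventions and parameter choices behind
`imctme`, in the order data flows through the pipeline, together with what
the synthetic generator does and does not emulate.

## Spillover compensation

Mass channels bleed into one another (isotopic impurity, oxide formation).
The correction assumes a per-pixel linear forward model: observed vector
`o = Sᵀ t` with `S[s, t]` the fraction of source channel `s` seen in
target `t` (diagonal 1, off-diagonal in [0, 1)). Compensation solves
`argmin_{t≥0} ‖Sᵀt − o‖₂` independently per pixel — no spatial coupling.
Implementation detail: all pixels are first solved by one batched
unconstrained least squares; only pixels whose unconstrained solution has
a negative component are re-solved by true NNLS. The result is identical
to per-pixel NNLS and orders of magnitude faster on megapixel stacks.

## Nuclear projection and smoothing

Segmentation runs on a single image built from the nuclear channels
(histone H3 and the two iridium DNA intercalators by default). Each
channel is min-max rescaled to [0, 1] — the normalization that makes
channels of different sensitivity commensurable before a maximum
projection; constant channels map to zero so they cannot dominate the
max. The projection is median-filtered with a 2×2 window (top-left
anchored, reflective boundary; any consistent anchoring works, this one
is fixed and documented) and Gaussian-blurred with σ = 2 px, truncated at
4σ. "Kernel width 2" is read as σ = 2 px; both the window and σ are
configurable. Note that a 2×2 median removes isolated single-pixel
impulses by construction — that is its despeckling purpose.

## Watershed segmentation

Foreground is Otsu-thresholded on the smoothed projection; seeds are
local maxima at least `min_seed_distance` = 5 px apart (4 px suits
sparser tissue); watershed runs on the negated intensity within the
foreground. Blank images yield empty masks rather than errors. The
defaults are deliberately plain — the watershed's role here is to produce
*weak labels* for an external instance-segmentation model, not to be the
best segmenter.

## Weak-label export

A mask + image pair is cut into a rows×cols grid (default 4×4; remainder
rows/columns fold into the last tile, so 31 images always give 496
tiles). Instances are clipped at tile borders; fragments below 10 px are
dropped to avoid degenerate training boxes. Tiles serialize as COCO-style
annotations (single category `cell`, uncompressed column-major RLE).

## Dice evaluation

Every cell `x` of the evaluated mask is matched to the reference cell `y`
maximizing `|x∩y|` (ties to the smallest reference label, for
deterministic reports); Dice = `2|x∩y|/(|x|+|y|)`, 0 when `x` overlaps
only background. Matching is independent per evaluated cell — a reference
cell may be the best match of several — since per-cell quality, not a
bijective assignment, is being scored. Methods are compared by paired
two-sided *t* tests on per-sample Dice means and, separately, standard
deviations; zero-variance paired differences are flagged degenerate
instead of producing a p-value.

## Phenotyping

Marker quantification is the mean raw intensity over each cell's mask
pixels; centroids are unweighted pixel-coordinate means (x = column,
y = row, origin top-left, scaled by pixel size to µm). Intensities are
z-scored per image and marker with the *population* standard deviation
(the normalization is over the finite set of cells on one image);
constant markers get z = 0 so they cannot poison marker-space distances.

Clustering follows the PhenoGraph construction: Euclidean kNN graph on
the z-scored marker vectors, edges re-weighted by the Jaccard overlap of
neighbor sets, Louvain community detection at the highest-modularity
level with a fixed seed. Cells are canonically ordered by
(sample_id, cell_id) before graph construction, making the partition
invariant to input row order. The distance metric and Louvain variant
are conventions, exposed in the protocol config.

A multi-round protocol first under-clusters with a large k to separate
major populations, then applies *pool rules* — threshold predicates on
cluster-median z-scores — to route whole clusters into named pools that
later rounds re-cluster with their own marker lists and k. Rounds whose
pool is empty or smaller than k+1 are skipped with a warning; cells are
never added or dropped. Terminal clusters are named by ordered
first-match-wins annotation rules on median z-scores; a cluster matching
no rule is an error that prints its medians. k for re-clustering rounds
defaults to 30 where no value is dictated by the data.

## Tumor-enriched region and spatial features

The region is the level set of a kernel density estimate: unit impulses
at the pixel-rounded centroids of tumor cells, convolved with a
*unit-mass* 2-D Gaussian (σ = 15 px), thresholded at 0.0005 cells/px²
with `≥` comparison. Under these constants a single isolated tumor cell
peaks at 1/(2π·15²) ≈ 7.07×10⁻⁴ and carries a region disk of radius
≈ 12.5 px — the unit-mass kernel is the only normalization under which
the σ and threshold constants are mutually consistent. Centroids are
rounded because the density map lives on the pixel grid.

Density of subtype *s* = (in-region count of *s*) / (total tumor cells of
the sample). Non-tumor densities may exceed 1; a sample with no tumor
cells has undefined features and raises.

Two cells are nearest neighbors when their centroid distance is strictly
below 20 µm. The pair search uses a k-d tree but filters exact distances,
so it equals the all-pairs result including the boundary case.
Avg.C ₘʲ = N*ₘⱼ*/N*ₘ*: N*ₘ* counts in-region *m*-cells; N*ₘⱼ* counts
ordered neighbor pairs whose *m*-role endpoint is in-region — the partner
is deliberately unrestricted, making Avg.C the literal average count of
*j* cells around an in-region *m* cell (a stricter both-in-region
convention is available behind a flag). Self-pairs (m = j) count once per
ordered role. Avg.C is missing (NaN) when N*ₘ* = 0; for modeling, missing
values are imputed as 0, since the absence of the anchor subtype is
itself informative and the classifier needs complete rows.

Group comparison uses classic pooled-variance unpaired *t* tests (Welch
available via config), Benjamini–Hochberg adjusted across all features
tested in the run; features missing in more than half the samples are
excluded and logged.

## Survival cascade

The split takes `floor(0.8 · min(class sizes))` samples per class into
training (random under-selection in the larger class enforces parity;
with 21+20 that is 16+16 train, 5+4 test, test ratio 1.25). The Spearman
filter target is the binary class label by default (survival months
available as an alternative — which of the two a "correlation with
survival" means is genuinely ambiguous, so both are supported). Features
with |r| ≤ 0.2 or undefined r drop. Decorrelation visits features by
descending |r vs target| (name as tie-break) and drops any feature with
pairwise |Spearman| ≥ 0.65 to an already-kept one, recording the keeper.
Scaling is min-max on training statistics, test values clipped to [0, 1],
constant features to 0. RFE removes one feature (smallest |coefficient|)
per refit of an L2 logistic regression (C = 1.0, with intercept — the
penalty stabilizes coefficients at n ≈ 32); leave-one-out accuracy is
computed for every top-n prefix of the ranking and the smallest n
maximizing it is chosen. Held-out metrics: accuracy, sensitivity (LTS
recall), specificity (STS recall), ROC by midrank convention, trapezoidal
AUC. Every stage appends to a selection trace from which the final
feature pool is exactly reproducible.

For interaction-feature runs, a family pre-filter keeps Avg.C features
whose anchor or partner subtype is in the prognostic density set and
whose group comparison is BH-significant, mirroring how the density and
interaction analyses feed each other.

## Omics link

Probes collapse to the single highest-variance probe per gene
(lexicographically smallest probe on ties); unmapped probes pass through
flagged. Gene–density association is Spearman r with two-sided p over the
shared samples (≥ 5 required), flagged at |r| > 0.4 and p < 0.05. The
sign is always reported; a strict positive-only mode exists behind a flag
because requiring "positive" correlation while thresholding |r| are both
plausible readings. Cell-type filtering is plain set intersection with
user-supplied gene lists (e.g. scRNA-seq-derived fibroblast or epithelial
sets), optionally intersected with a secreted/receptor annotation except
for named exempt subtypes (the CAF subtypes and the B7H4⁺ tumor subtype,
where the full transcriptome is of interest).

Best-cutoff Kaplan–Meier scans expression quantiles 10%–90% in 5% steps
(grid configurable), skips cutoffs leaving fewer than 4 patients in
either arm, computes the standard two-group log-rank statistic at each,
and reports the cutoff with the smallest p **together with the scan trace
and an explicit caveat**: minimizing p over a scan is anti-conservative,
and the null simulation in the test suite shows the selected p clears
0.05 far more often than 5% of the time. Treat scan p-values as ranking
scores, not calibrated significance.

## Synthetic data: what it emulates and what it does not

Tissues are axis-aligned ellipse cells (radius jitter) on a pixel grid;
tumor subtypes concentrate around a few nest centers (Gaussian spread),
non-tumor subtypes disperse uniformly; overlaps resolve by later-label-
wins, with the guarantee that every cell keeps at least one pixel so mask
labels, ground-truth cells and quantified rows stay 1:1. Pixel
intensities are Poisson draws around a per-cell mean (gamma jitter with
CV = the profile's dispersion) — the counting-statistics structure of ion
detection, not its physics (no isotope abundance, detector dead time, hot
pixels, or spatial intensity gradients). An optional soft minimum
centroid spacing supports low-overlap scenarios; the default keeps
overlap on, because segmentation must tolerate it.

Cohorts default to the study composition of 21 LTS + 20 STS samples.
Planted *density* effects shift a subtype's mixing weight half up in LTS
and half down in STS (default: +0.10 on the cytotoxic T-cell subtype).
Planted *interaction* effects re-place a fraction (default 0.6) of the
anchor subtype's cells near nest-core partner cells, 3–8 px away — a
short-range rearrangement that moves Avg.C without (materially) moving
the region or the densities, so the two feature families carry separable
signals. Survival months are uniform within class-consistent ranges
(LTS ≥ 60, STS ≤ 20), ages normal per class. Seeding is hierarchical —
`SeedSequence([seed, class, index])` per sample — so growing a cohort
never perturbs existing samples.

Expression matrices plant Spearman targets by mixing the density's
normal scores with independent noise, with the mixing weight calibrated
by bisection against the realized sample correlation (rank noise at
n = 26 has an SE near 0.2, far larger than the ±0.15 contract the
planted genes must meet); |r| = 1 targets use exact monotone transforms.
Noise genes are i.i.d. normal.

Because the generator's subtypes are well-separated in marker space and
its effects are planted directly in the quantities the pipeline measures,
passing tests demonstrate the *machinery* — correctness of the statistics
and recoverability of effects of the stated size at the stated n — not
performance on real tissue, where marker overlap, segmentation errors and
batch effects dominate.

## Problem sizes and determinism

Default synthetic images are 300×300 px with 250 cells (the package's
choice of desk-scale conditions; acquisition-scale images of
1000×1000 px with ~4000 cells run through the same code path).
Cohort-level experiments in the test suite use 25 replicate seeds for
recovery rates and 8–15 for AUC and calibration summaries. All
randomness flows from explicit integer seeds; identical seeds give
byte-identical tissues, cohorts and matrices.

## Known limitations

- The watershed is a baseline segmenter; its weak labels inherit its
  merge errors, which an external model trained on them can only partly
  overcome.
- Avg.C is a ratio of small counts in small regions; its variance is
  large for rare subtypes, and missing-as-zero imputation biases toward
  "no interaction" for sparse anchors.
- The best-cutoff log-rank p is anti-conservative by construction (see
  above).
- The decorrelation stage keeps exactly one representative of each
  correlated group: a near-duplicate of a causal feature may be kept in
  its place, so chosen-feature identities should be read as equivalence
  classes, not single causal columns.
- Synthetic tissues do not model cell-shape diversity, stromal
  architecture, imaging artifacts, or marker spillover beyond the linear
  model.
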