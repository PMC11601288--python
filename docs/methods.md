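# Methods

## Coordinate frames and conventions

Three frames appear in the pipeline: imaging pixels (0-based, x along
columns), the spot frame in micrometres, and the low-resolution raster used
for mask registration. Points are `(x, y)`; intervals are half-open
everywhere, so a cell on a spot's low edge belongs to it and one on the high
edge does not, and no point can belong to two spots. The pixel↔micrometre
scale is never inferred from data; it is carried by the fitted similarity
transform (whose scale factor absorbs the unit change) or set in the
configuration.

## Per-cell protein quantification

Features are extracted by summing each marker channel over each cell's
pixels. Cells are filtered to the inclusive [0.05, 0.95] area-quantile band
and strictly above the 0.1 quantile of raw DAPI; both quantiles are computed
on the unfiltered table, with linear interpolation between order statistics
(the `numpy` default — any fixed definition would do, but it must be fixed
for reproducibility). If DAPI is constant the strict rule would discard every
cell; that degenerate case keeps all cells and warns instead, on the view
that silently emptying a dataset on a tie is worse than skipping one filter.

Scaling maps each marker's 0.05 quantile to 0 and 0.95 quantile to 1,
clipping outside. Optionally (default on) each cell's sums are divided by its
area first, turning totals into mean signal densities; both behaviours are
supported because total and density conventions are both common in
multiplexed imaging and the appropriate one depends on the segmentation
quality. A marker with coincident anchors is scaled to zero and flagged.

## Registration

Silhouette extraction: Gaussian smoothing (default σ = 5 px), Otsu threshold
over a 256-bin histogram, binary hole filling. The spot side is rasterised at
10 px per channel pitch. Two raster modes exist: `fill="width"` draws each
spot at its true channel width (the faithful, disjoint geometry used for
geometric checks), while `fill="pitch"` lets each tissue-covered spot fill
its pitch cell. Registration uses the latter: a solid tissue silhouette
cannot be matched to a sparse checkerboard under a squared-error loss — the
optimizer just shrinks the moving mask into nothing.

The similarity transform (rotation, uniform scale, translation; no
reflection unless requested, since sections are not mirrored in this
workflow) minimises the mean squared difference between the warped moving
mask and the fixed mask. The loss is evaluated on Gaussian-blurred (σ = 2 px)
float renderings; a strictly binary loss is flat almost everywhere and
defeats local refinement. Optimisation: moments of the binary masks give a
closed-form seed (centroids → translation, RMS radii → scale, principal axes
→ rotation up to the 180° ambiguity, which is searched explicitly); a coarse
grid over ±20° and ±25 % scale around the seed picks the basin; Nelder–Mead
polishes. On noiseless fixtures this recovers a (10°, 1.2×, (30, −15) px)
warp to within (0.1°, 0.1 %, 0.1 px), comfortably inside the (±1°, ±2 %,
±2 px) band the tests assert. The optimiser, bounds and loss discretisation
are this package's choices; only the loss criterion itself (squared error
between transformed masks) is inherent to the method.

Landmark affines (for cross-section QC, where ~6 manually picked point pairs
are available) are ordinary least squares on the homogeneous design matrix,
with per-point residuals reported; at least three non-collinear pairs are
required.

## Spot grid and composition

The chip has `n_a × n_b` channels (50 × 50 standard; simulations default to
20 × 20) of width 10–50 μm. The pitch defaults to twice the width — equal
channel and gap — and is configurable because fabrication specs vary and the
gap is not recoverable from the count matrix. Cells are assigned to the spot
whose square contains their centroid; area-overlap apportionment was
rejected because it would place one cell in several spots and the downstream
formula treats cells as indivisible. Composition βᵢₖ = nᵢₖ / nᵢ is defined
only for spots with at least one assigned cell; cell-free spots are flagged
undefined and skipped by splitting, never silently zero-filled, because
β = 0 ("we know there is nothing here") and β undefined ("we saw no cells")
license different conclusions.

Spots present in the count matrix are tissue-covered by definition (tissue-
free positions are excluded upstream when the matrix is generated); grid
positions absent from the file are treated as non-tissue.

## Reference profiles and splitting

μₖⱼ is the per-type mean of reference cells, each first scaled to the median
library size (mode `"raw"` skips this). Normalisation before averaging
prevents deeply sequenced types from dominating the profile; the mode is
recorded in the output so the provenance of μ is always explicit.

Splitting applies x̂ᵢⱼₖ = xᵢⱼ βᵢₖ μₖⱼ / Σₖ′ βᵢₖ′ μₖ′ⱼ per spot and gene,
emitting sub-spots only for types with βᵢₖ > 0. Raw counts are accepted as
xᵢⱼ and the choice is recorded in the report; the formula is scale-free in x
so normalised input would simply yield normalised sub-spots. Genes absent
from the reference are dropped (counted); a type present in β but missing
from μ is an error naming the type. When a gene's denominator is zero in a
spot but xᵢⱼ > 0 (all types with β > 0 have μ = 0 for that gene), the default
fallback distributes the count proportionally to β — conserving mass and
avoiding discarded counts — while `fallback="drop"` zeroes it; either way the
affected genes are logged for audit. Conservation Σₖ x̂ᵢⱼₖ = xᵢⱼ holds by
construction in both branches and is verified at 1e-9 relative tolerance
over whole simulated datasets.

Sub-spot protein profiles are means of the scaled marker vectors of each
spot's cells of that type; the sub-spot coordinate is the member-cell
centroid (an implementation decision — nothing downstream depends on it
beyond plotting). The paired RNA/protein matrices are written with identical
row order (MatrixMarket + sidecars for RNA, CSV for protein and metadata);
sub-spots lacking an imaging partner are excluded and counted.

## Label transfer

Pivot cells — the ~10 % of imaging cells with high-confidence cross-modality
matches — carry transferred type labels; a linear multiclass SVM (squared
hinge, C = 1, standardised features) trained on their scaled protein
profiles annotates the rest. A stratified 20 % holdout yields per-class F1
scores reported alongside the model; the final model is refit on all pivots.
Softmax over decision values provides per-class scores for reporting only;
labels come from the argmax of the raw decision function. At least two
classes with five pivots each are required.

## Cross-section QC

Two cell tables are brought into a common frame by the landmark affine, cell
positions are binned at 100 px (default, configurable), per-bin marker means
are compared by Pearson correlation over bins present in both datasets (at
least three required). Bins anchor at the frame origin and negative
coordinates floor toward −∞. A marker constant over the common bins gets
r = NaN with a flag rather than a fabricated value.

## The synthetic world

The generator states one fixed world and the tests measure the pipeline
against it:

- tissue: a connected, hole-free union of overlapping discs covering 20–80 %
  of a 256 px frame;
- cells: 2,000 centroids uniform over tissue pixels (distinct pixels,
  sub-pixel jitter); types i.i.d. from proportions (0.4, 0.3, 0.2, 0.1);
  areas lognormal(log 120, 0.35) px² (so the size filter bites); marker
  intensities mean-preserving lognormal (σ = 0.25) around a near-diagonal
  panel (one bright marker per type at 100, off-target 10, DAPI 50 shared) —
  the idealised outcome of a well-chosen antibody panel;
- grid: 20 × 20 spots, 25 μm wide at 50 μm pitch; the true imaging→grid
  transform is a 5° tilt with scale 4.5 μm/px;
- counts: xᵢⱼ ~ Poisson(dᵢ Σₖ nᵢₖ pₖⱼ) with p the row-normalised true
  type-by-gene means (gamma(2, 1) draws over 200 genes) and dᵢ = depth/nᵢ so
  the expected spot total is 2,000 UMI. Counts are drawn per type and summed,
  so the realised per-type contribution is known exactly and recovery can be
  scored against it.

What the generator does **not** emulate: segmentation errors (label masks are
rendered as a nearest-centroid partition, so segmentation is perfect by
construction), marker spillover and background, spatial autocorrelation of
expression, batch effects, and cell-type-dependent capture efficiency. A
green test therefore establishes that the implementation is faithful to the
stated model — not that the model captures every pathology of real data.

## Numerical choices

- β rows must sum to 1 within 1e-12; conservation is checked at 1e-9
  relative.
- Quantiles: linear interpolation, everywhere.
- Registration tolerances: identity within (0.5°, 1 %, 1 px); generic warp
  within (1°, 2 %, 2 px); the recovered optimum is additionally required not
  to exceed the generating transform's loss by more than 1e-6.
- Seeds are explicit function arguments; there is no global random state.
  Derived seeds (seed+1, seed+2, …) keep stages independent under one master
  seed.

## Known limitations

- Mask registration assumes the two silhouettes overlap after the moment
  seed; wildly different fields of view need a manual initial guess.
- The splitting formula attributes counts proportionally within a spot; it
  cannot recover within-type expression heterogeneity across cells of one
  spot, and correlated errors in β propagate directly into x̂.
- The label-transfer SVM is linear; panels whose types are only nonlinearly
  separable in protein space would need a kernel or a different classifier.
- The CLI `run-all` is wired to the directory layout `simulate` writes; real
  datasets use the stage subcommands individually.
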