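# Methods

This note documents the models, conventions and numerical choices behind
`cryptscape`, and what its synthetic benchmarks do and do not demonstrate.

## The measurement model

The object of study is the en-face geometry of colon mucosa in SHG images:
dark elliptical crypt lumens embedded in bright fibrillar-collagen walls.
Fibrosis presents as fewer, larger, more widely spaced crypts, so the
pipeline reduces an image to a small set of physical quantities per crypt
(area in µm², border-to-border distance to every other crypt) and per image
(interior crypt count, mean area, mean nearest-crypt distance, mean
neighbor count).

All geometry is pixel-based. An object's boundary is the set of its pixels
with at least one background 8-neighbor (the image edge counts as
background), and the distance between two crypts is the minimum Euclidean
distance between boundary *pixel centers*, scaled by the pixel size. No
sub-pixel contour interpolation is attempted: pixel-center distances make
every value exactly reproducible and exactly testable against a brute-force
oracle. A consequence worth knowing: two distinct 8-connected objects can
never be closer than 2 pixels, and all distances are quantized at the pixel
level, so distances carry an uncertainty of order ±1 px relative to the
underlying continuous geometry.

Two radii matter and are deliberately different in kind:

- **Nearest-crypt distance, 40 µm search radius.** The nearest-crypt
  distance is *undefined* (not truncated) when no other crypt lies within
  40 µm; undefined values are excluded from per-image means, and the count
  of contributing crypts is reported. The alternative readings (truncation
  at 40, or unbounded search) are not used; this choice is visible in the
  `n_nn_defined` field of every summary.
- **Neighbor count, 20 µm radius, inclusive.** The neighbor test uses
  d ≤ 20 µm; the nearest-crypt cutoff likewise uses ≤ 40 µm. Inclusive
  bounds at round physical radii are fixed so results are exact.

Crypts touching the image border are flagged, excluded from all per-image
statistics (their size and spacing are censored by the field of view), but
retained as distance and neighbor partners of interior crypts. Their rows
remain in the per-crypt table for transparency.

### Sensitivity of the nearest-distance mean to the 40 µm cutoff

Because undefined values are excluded rather than truncated, the per-image
mean nearest distance depends discretely on which crypts fall inside the
search radius. A segmentation that dilates lumens by half a pixel can move
a true distance of 40.2 µm to 39.6 µm, flipping that crypt's inclusion and
shifting the image mean by more than the boundary displacement itself. In
the recovery benchmarks this occasionally produces mean-distance errors
above 1 px even when every individual distance is recovered to sub-pixel
accuracy; users comparing conditions should prefer paired comparisons of
the same fields or report `n_nn_defined` alongside the mean.

## Segmentation

1. **Max projection** over z (the analysis is 2D by design; crypt spacing
   is an en-face quantity).
2. **Crypt probability.** A two-stage linear-logistic pixel classifier over
   a fixed feature bank: per scale σ ∈ {1, 2, 4, 8} px, the
   Gaussian-smoothed intensity, Gaussian gradient magnitude, and local
   variance (E[x²] − E[x]² under the same window), with reflective
   boundaries. Features are standardized with training-set moments stored
   in the classifier. Stage 2 appends Gaussian-smoothed stage-1
   probabilities (one per scale) and refits — spatial context ("this pixel
   sits inside a region that already looks like lumen") sharpens the
   decision without any architectural machinery. Fitting uses regularized
   logistic regression (C = 1, L-BFGS, tight tolerance) on sparse labeled
   pixels; inference is an explicit stored-weights sigmoid, so a serialized
   classifier JSON is self-contained. Users with their own pixel
   classifier can bypass this entirely and supply a probability TIFF.
3. **Hysteresis thresholding.** A pixel is selected iff p > low and it is
   8-connected through pixels with p > low to a seed with p > high.
   Strict inequalities at both levels are fixed for exactness (ties at a
   float threshold are measure-zero). Defaults low/high = 0.5/0.8 are
   configuration, not a claim about any particular dataset; both are
   overridable everywhere.
4. **Post-processing.** 8-connected labeling (4-connectivity for
   background when detecting holes — the standard complementary pair);
   background cavities enclosed by exactly one object are filled into it,
   iterated to a fixpoint; objects with filled area < 300 µm² are
   discarded; cavities whose only remaining owner is a surviving object
   (possible after removals) are filled again; labels are renumbered by
   descending area. The second fill makes the whole operation idempotent —
   running it on its own binarized output changes nothing — while keeping
   the stated order "fill first, then size-filter on the filled area".
   Holes bounded by more than one label are left open: filling them would
   require an arbitrary owner.

## Contours and the update mode

Automatic segmentation is imperfect; the workflow therefore saves crypt
contours to a versioned, hand-editable JSON file and recomputes every
measurement from the (possibly edited) file. Polygons are stored on pixel
*corners*: the vertices are integer grid coordinates and a pixel belongs to
an object iff its center (row + 0.5, col + 0.5) lies inside the outer
ring(s) and outside the holes. Because centers sit at half-integers and
ring edges run along integer grid lines, rasterization is exact and
save→load reproduces the label map bit for bit — including single-pixel
objects and diagonal-only connections, which pixel-center polygon schemes
cannot represent unambiguously. Merged, split, deleted or moved polygons
load into a valid, contiguously relabeled map (a polygon that rasterizes
into several 8-connected components becomes several labels); overlapping or
self-intersecting polygons are rejected with a message; objects that fall
under the size filter after editing are dropped with a warning.

## The fast distance computation and its oracle

Pairwise border-to-border minima are computed with one exact Euclidean
distance transform per label (from its boundary pixels), reading the
transform at the other labels' boundary pixels — O(K·N) instead of the
O(B²) all-pairs scan, and exactly equal to it because the transform is the
exact Euclidean one. The brute-force oracle (`synthetic.gt_metrics`)
deliberately keeps the O(B²) scan with no shortcuts; the test suite and the
reproduction script assert exact `DataFrame` equality between the two on
hundreds of random maps. The tie-break when two crypts are equidistant is
"smaller label wins" in both paths.

## The synthetic mosaic generator

The generator emulates the *geometry and contrast* of en-face SHG mucosa,
not its optics. Elliptical lumens (axis ratio ≤ 1.3) are placed by dart
throwing; a candidate is rejected if any of its pixels lies within
`min_gap_um` of an already placed lumen (pixel-center distances — the same
metric the analysis measures, so the generator's spacing parameter is
directly recoverable). Placement failure after 10,000 attempts per crypt
raises with the number that did fit. Walls are rendered as bright bands of
fixed thickness (default 6 µm) around the lumens, carrying a band-pass
noise texture smoothed along the local wall tangent (computed from the
lumen distance map) — SHG-like striations that wrap around crypts and give
the classifier realistic structured clutter. Additive Gaussian noise tops
it off; intensities live on the 8-bit scale with defaults wall 190,
background 60, lumen 25.

Defaults mirror the imaging conditions the pipeline targets: a 1024 × 1024
field at 0.41625 µm/px (≈ 426 µm across) with ~40 crypts of 12 µm lumen
radius. The benchmark experiments use scaled-down fields (300–400 µm at
1 µm/px, 14–35 crypts) so the full train–segment–measure loop runs in
seconds; these sizes are the package's chosen test conditions and are
recorded with each result.

The fibrosis transform maps severity s ∈ [0, 1] to fewer
(× (1 − 0.5 s)), larger (× (1 + 0.6 s)) and more widely spaced
(gap × (1 + 1.5 s)) crypts; s = 0 is the identity and all three fields are
monotone in s. The factors set the *direction* and a plausible magnitude of
the fibrotic phenotype; they are not fitted to any dataset.

What passing synthetic benchmarks shows: the implementation measures what
it claims to measure — known spacing is recovered through the full
classifier + segmentation path, the metrics agree exactly with exhaustive
computation, and the phenotype contrast moves every summary in the expected
direction. What it does not show: performance on real SHG images, whose
walls break, vary in thickness, and share intensity with debris and
submucosal collagen; no point-spread function, depth attenuation or
illumination gradient is simulated. Real deployments should validate the
classifier per imaging protocol and use the contour update mode for manual
correction.

## Collagen-covered area

"Enhance white detail (size 2)" is a proprietary operator of the original
acquisition software; here it is an *additive white top-hat* — image plus
its top-hat under a disk of radius `size`, clipped to the dtype range — a
standard small-bright-structure enhancer consistent with the operator's
name and size parameter, documented as a stand-in. Histogram stretch maps
the observed min/max linearly onto the dtype range (constant images pass
through). "Median (size 1)" is read as radius 1, i.e. a 3 × 3 window —
the conventional meaning of a size parameter in filter UIs. The threshold
is fixed and user-supplied (the original was set manually); no automatic
threshold selection is offered. Stacks are processed slice-wise with the
per-slice table exposed and the headline numbers are means over slices.
Covered fraction is non-increasing in the threshold by construction.

## Matrisome statistics

Symbols are matched by case-insensitive string equality after uppercasing
and whitespace stripping; duplicates are dropped and counted. No ortholog
mapping is attempted for cross-species comparisons — uppercased symbols
coincide for most matrisome genes, and every non-matching symbol remains
listed in the difference sets so the decision is auditable. The DE filter
keeps proteins with fold change > 1.5 in *either* direction
(max(r, 1/r) > 1.5 on a ratio r) at step-up FDR ≤ 0.1; the fold-change
bound is exclusive and the FDR bound inclusive (the printed cutoff is
ambiguous between ≤ and <; ≤ is the fixed convention here). "Step-up" is
Benjamini–Hochberg. The two-factor per-protein test is a type-II two-way
ANOVA reporting the main effect of the factor of interest (genotype);
single-level second factors route to the unpaired two-sided t-test;
proteins with zero variance in every cell are flagged with undefined p.

## Cohort statistics

Image summaries are averaged per mouse with equal weights before any group
test — the animal is the unit of inference; images where a metric is
undefined are excluded from that metric's mean with the contributing count
reported. Group comparisons use Welch's unequal-variance two-sided t with
Welch–Satterthwaite degrees of freedom; correlations with tumor burden use
the sample Pearson r with the two-sided t-transform p. Both are verified
against closed-form recomputation to 1e-10 and the Welch test's type-I
error is calibrated by null simulation (unequal variances, n = 8 per
group). Outliers are flagged by an iterative two-sided Grubbs test at
α = 0.05 — a documented stand-in for "statistically significantly
different from the group average" — and are never removed automatically;
degenerate cases (zero variance, all-equal groups, constant paired
differences) return explicit flagged results rather than NaNs.

## Known limitations

- The pixel classifier is linear; heavily textured or uneven illumination
  may need an external classifier via the probability-map escape hatch.
- The 40 µm exclusion rule makes the mean nearest distance discontinuous
  in segmentation perturbations (see above).
- Heatmap rendering fixes viridis with reserved grays for border crypts
  and undefined values; the palette is metadata in every color table.
- 3D (z-resolved) segmentation is out of scope; the analysis operates on
  the max projection by design.
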