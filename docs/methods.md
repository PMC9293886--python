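# Methods

## Problem setting

Punctate fluorescent structures in yeast — stress granules especially —
sit on a bright, variable cytoplasmic background, and deciding which
local intensity perturbations are *bona fide* foci is subjective. The
package separates the problem into a deterministic geometric part
(finding candidate blobs and their boundaries without tunable thresholds)
and a supervised part (deciding which candidates count, learned from
labels or expressed as explicit feature bounds).

## Candidate detection by contour loops

All contouring operates on the per-cell min-max-normalized max-projection
patch, so intensities live in [0, 1] regardless of camera gain or
exposure. Closed marching-squares iso-contours are extracted at
`n_levels` (default 64) evenly spaced levels in (0, 1); only loops lying
entirely inside the cell mask are kept. Because level sets of a single
image never cross, the loops form a forest under containment: any two are
nested or disjoint.

A focus candidate is a pair (outer C_k at level I_k, inner C_j at level
I_j > I_k) with perimeter(outer) ≤ L_max and perimeter(inner) ≥ L_min.
The inner loops are the *innermost qualifying* loops — those containing no
other qualifying loop at a higher level — so one intensity peak yields
exactly one candidate. Each inner is paired with its outermost qualifying
container; nearby peaks may share an outer and become separate candidates
that the boundary step later merges or keeps. The length bounds are the
only experimenter-set parameters and are deliberately loose: they bound
which blobs are considered at all, not where their boundaries fall.

## Curvature-maximum boundaries

For each candidate the enclosed area a(I) of the contour containing the
inner loop is sampled at `n_eval` (default 32) levels in [I_k, I_j]. The
map r(I) = √(a(I)/π) converts it to an equivalent-radius profile, exact
for circular foci and an area-faithful approximation otherwise. Inverting
the (monotone) map gives the radial intensity profile I(r), and the final
outline is the contour at the level where d²I/dr² is maximal. The
curvature maximum exists even for profiles with no inflection point
(e.g. cone-like peaks), and for a Gaussian of width σ it sits at radius
√3·σ, which the tests verify to within 10 % for σ ∈ {2, 3, 4, 5} px.

Numerics: a(I) is first made monotone by a running minimum (sampling ties
at neighboring levels are flattened), I(r) is resampled on a uniform
64-point radius grid, and the second derivative is estimated with a
Savitzky–Golay quadratic fit whose window adapts to the largest sample
gap in r. Piecewise-linear interpolation concentrates all curvature at
its knots; a local parabola spanning several knots recovers the
underlying profile's curvature instead of the kinks. The half-window edge
points are excluded from the argmax; exact ties prefer the lower
intensity (the larger contour). Fewer than 5 usable area samples trigger
a midpoint-intensity fallback that is flagged on the resulting outline.

Candidates whose final contours overlap are one focus: contours at one
level cannot cross, but two candidates can land on different optimal
levels whose contours nest, so merging clusters outlines by polygon
overlap and keeps each cluster's outermost contour. This reproduces the
saddle behavior checked in the tests: two equal Gaussian peaks merge
exactly when the optimal intensity falls below the numerically computed
saddle level between them. An optional `area_scale` factor radially
rescales final contours about their centroids for users whose size
convention differs; the default 1.0 leaves outlines untouched.

## Cell segmentation

Brightfield cell edges are ridge-like. Frangi vesselness over scales
1–3 px is thresholded (0.05 by default; the `black_ridges` flag selects
dark-edged modalities), blobs outside configured area / eccentricity /
solidity bounds are removed, and the surviving outlines are thinned to a
skeleton. Candidate cell centers are pixels whose distance to the
skeleton lies in [r_min, r_max] (cell-size bounds, configured in nm); for
each, an ellipse is least-squares fitted to skeleton points within r_max
and scored by the summed squared point-to-ellipse distance (algebraic
distance normalized by its gradient). Candidates whose surrounding
skeleton leaves an angular gap exceeding 25 % of the circle are dropped —
this exact-gap criterion, rather than counting occupied angular bins,
cleanly rejects open arcs whose partially filled edge bins would
otherwise pass. Local minima of the Gaussian-smoothed (σ = 1 px) score
map, deduplicated within r_min, are the cell hypotheses.

Each fitted ellipse is snapped to the boundary by a greedy active
contour: every vertex searches ±3 px along its normal for the position
maximizing edge strength, penalized by deviation from the neighbor
midpoint (elasticity) and discrete curvature. Edge strength defaults to
the brightfield intensity itself because the ridge crest *is* the
boundary; a gradient-magnitude image can be supplied for step-edged
modalities. Contours on flat images or with out-of-bounds areas are
rejected (flagged, not raised — batch runs skip them). Externally
produced masks can bypass segmentation entirely. The whole chain is
seed-free and deterministic.

On noiseless synthetic brightfield scenes of ≤ 10 separated cells the
chain recovers every cell with IoU ≥ 0.9 (typically ≥ 0.97).

## Features and classification

Twelve numbers in eight feature groups describe each detected focus:
max/min/mean normalized intensity inside the outline; area, eccentricity
and solidity of the rasterized outline; area relative to the cell; mean
boundary intensity of the predicted outline and of the outer contour,
each as a ratio to the center intensity (the maximum inside the inner
contour — "center" is otherwise undefined for irregular foci); their
absolute difference; centroid distance to the cell centroid normalized by
the cell's equivalent radius; and the within-cell brightness rank mapped
to [0, 1] (a lone candidate ranks 1). Features are computed on normalized
patches, making them exactly invariant to affine intensity rescaling;
exported brightness statistics always come from raw pixel values.

The matrix is whitened per feature (zero mean, unit variance) and min-max
rescaled to [0, 1]; zero-variance features map to 0.5. The scaler is part
of the stored model and reapplied verbatim at prediction time. The
classifier is an RBF-kernel SVM (`FocusSVC`, a scikit-learn-compatible
estimator) with defaults C = 1 and gamma = "scale"; a logarithmic grid
search over C ∈ [1e-3, 1e3] and γ ∈ [1e-8, 10] maximizing sixfold CVMCC
is available but typically improves little over the defaults. Models
serialize to a single JSON file (scaler, support vectors, dual
coefficients) so they can be shared and reloaded without pickle.

Evaluation uses the Matthews correlation coefficient with the standard
zero-denominator → 0 convention; folds are label-stratified and seeded.
The random quantifier matches per-cell selection counts but samples
candidates uniformly without replacement, scoring ≈ 0 over 50
repetitions — the chance floor against which trained models are compared.
Single-class training data raises an error pointing to the threshold
pipeline, which labels a candidate positive iff every bounded feature
lies inside its [lo, hi] interval.

## Colocalization

Channels must be extracted with identical cell outlines. Pearson
correlation is computed on raw in-mask pixels per cell and per focus
(undefined for constant channels or foci under 4 px, reported as
missing). For every cross-channel focus pair: centroid distance, boundary
distance as the minimum polygon edge-to-edge distance (0 when touching or
overlapping), polygon-intersection overlap area, and per-partner overlap
fractions; nearest neighbors are assigned by centroid distance. Distances
and areas are reported in px and in nm/nm² via the pixel size. Trend fits
(linear, power, exponential — the latter two by log-space regression)
return parameters and R² on the original scale. Manders coefficients and
Costes randomization are out of scope; only Pearson is offered.

## Synthetic scenes

The generator emulates the relevant structure of yeast microscopy data:
elliptical cells drawn as bright Gaussian-profile ridge rings on
brightfield; cytoplasmic background with optional dark vacuole discs;
foci as radial Gaussians amplitude·exp(−r²/2σ²) (a cone profile is
available for edge cases without inflection points) spread across z by a
Gaussian whose peak slice carries the full amplitude, so the noiseless
max-projection equals the analytic 2-D model exactly; additive Gaussian
noise (Poisson behind a flag). Identical parameters and seed give
bit-identical images, and every focus records its analytic
curvature-maximum radius √3·σ as ground truth.

Defaults follow the emulated imaging regime: pixel size 40.7 nm/px,
foci of σ ≈ 2–3.5 px (a focus radius of 4–5 px is typical, so 1 px is a
~25 % size error), cytoplasmic background 100 counts with bright foci
adding 120–180 and ambiguous ones 15–55. The labeled candidate fixture
used by the classifier tests renders ~10 candidates per cell across 65
cells (≈ 630 candidates), labels them with a noiseless rule on peak
brightness, and is the package's stand-in for a human labeling session.
What the generator does *not* model: point-spread blur and deconvolution
artifacts, spatially correlated noise, clumped or budding cells,
non-elliptical shapes, or uneven illumination. Passing tests therefore
demonstrate algorithmic correctness under the stated model, not
performance on any particular microscope's data.

## Problem sizes and determinism

Tests run on 56–180 px frames with ≤ 65 cells; the acceptance script uses
a 55-cell reference with ~13 candidates per cell, mirroring a typical
single-condition yeast experiment. All stochastic steps (scene noise,
fold assignment, the random quantifier) take explicit integer seeds; the
geometric pipeline itself has no randomness. Pipeline JSON artifacts
embed a configuration content hash, and equal hashes produce
byte-identical files.

## Known limitations

- The active-contour energy is a pragmatic greedy scheme, not a published
  formulation; it assumes ridge-crest boundaries and a good ellipse
  initialization.
- Marching-squares polygons underestimate the area of contours only
  ~1 px in radius (inscribed-polygon bias), so boundaries of near
  diffraction-limited foci are systematically slightly tight.
- Cells must be approximately elliptical and non-overlapping; clumped
  cells are rejected rather than split.
- Merged foci are reported as one object by design; no watershed-style
  separation exists anywhere in the pipeline.
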