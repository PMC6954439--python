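# Methods

This note documents the model behind `mitoshape`, the conventions chosen
where the field's terminology underdetermines the computation, and what
the synthetic validation does and does not establish.

## Pipeline model and assumptions

The pipeline treats a mitochondrial staining as bright structures on a
smooth background in a single calibrated 2D plane. Stacks are collapsed
by maximum-intensity projection before analysis — the standard choice
for network stainings, where tubes wander between focal planes and a
mean or sum projection would dilute them into the haze. Projection is a
real limitation: structures that overlap in Z merge in the projection,
and densely networked regions can fuse into single objects. Pixel size
must be isotropic in-plane and known in μm (from TIFF metadata or a
flag); every parameter below is specified in physical units and
converted through it, so results are comparable across magnifications.

**Background subtraction.** The rolling-ball background is the grayscale
morphological opening of the image with a non-flat spherical-cap
structuring element of radius 2.5 μm; the residual is clamped at zero.
The ball's height in intensity units equals its radius in pixels (the
ImageJ convention). An opening-based background is anti-extensive, maps
flat fields to zero and passes structures narrower than the ball — here
mitochondria (≲ 1 μm) against cytoplasmic haze (≳ 5 μm scale).

**Enhancement.** The flattened image is sharpened by subtracting
`log_weight` × the scale-normalised Laplacian-of-Gaussian response at
σ = 1 μm (so bright curvilinear structures gain contrast), min–max
rescaled to [0, 1], and locally equalised by CLAHE with 2.5 μm tiles.
Sharpening — rather than replacing the image by the filter response —
is essential for the size-based classification downstream: a pure
response image widens every sub-micron object to the ~1 μm filter
scale, after which no object can measure an equivalent radius below the
0.6 μm punctum/swollen cut. `log_weight` defaults to 0.5, large enough
to roughly double tube contrast while keeping the negative-lobe halo
around small objects below the segmentation threshold. The CLAHE clip
limit defaults to 0.01. A constant image is defined to enhance to
constant zero.

**Segmentation.** Yen's maximum-correlation threshold is computed on a
256-bin histogram of the enhanced intensities inside the cell region;
the returned cut is a bin edge, and foreground is strictly
greater-than (ties fall to background). Components are 8-connected
(appropriate for 1-px-wide diagonal tube sections; also the ImageJ
default), and components below `min_area` = 0.04 μm² are discarded —
a pixel-noise floor (≈ 4 px at 0.1 μm/px), not a biological constant.

## Feature conventions

Discrete estimators for "perimeter", "aspect ratio" and skeleton
geodesics are not canonical, so the following conventions are fixed and
mirrored exactly by the test oracles:

* **Perimeter / circularity.** P is the length of the 0.5-level
  marching-squares contour of the hole-filled object mask, after a
  3-point circular moving average of the contour vertices. Hole filling
  makes this the outer outline (ImageJ particle-tracing convention), and
  the vertex smoothing removes most of the staircase overestimate that
  raw crack-counting suffers: an ideal digital disc then measures
  C = 4πA/P² ≈ 0.98–1.0 at any radius, a 10×10 px square ≈ 0.89, and —
  critically — a *noisy* round object stays ≥ ~0.9 instead of dropping
  to ~0.75, which would leak round objects into the rod class through
  the C ≥ 0.8 roundness gate. C is clamped at 1 (tiny objects can
  otherwise exceed it).
* **Aspect ratio.** Major/minor axis of the second-moment best-fit
  ellipse of the binary pixel set (ImageJ "Fit Ellipse" analogue); a
  degenerate minor axis (collinear pixels) is floored at one pixel.
* **Minimum Feret diameter (MLE).** Rotating calipers over the convex
  hull of all pixel *corner* points: the minimal width of a convex
  polygon is attained flush against a hull edge, so scanning edges is
  exact. Corner points (not centres) make a 1-px-wide object one pixel
  wide rather than zero.
* **Extension (E).** The object mask is thinned
  (topology-preserving 2D skeletonization); skeleton pixels form a graph
  with 8-neighbour edges weighted 1 px (axial) and √2 px (diagonal);
  endpoints are skeleton pixels with exactly one neighbour; E is the
  maximum over endpoint pairs of the shortest-path distance. Skeletons
  with fewer than two endpoints (rings, single pixels) fall back to the
  maximum geodesic between any two skeleton pixels — half the cycle
  length for a clean ring. A single-pixel skeleton has E = 0.
* **Single-pixel objects** are defined to have AR = S = C = 1.

## Classification

Sequential rules, first match wins, every object classified
(puncta → swollen → filament → rod; rods are the fall-through
"intermediate phenotype" class). "Round" is C ≥ 0.8 and AR ≤ 2;
"compact" for swollen is the shape surrogate S ≥ 0.9 (per-object
intensity compactness is not used). The size split between punctum and
swollen is the equivalent radius r_eq = √(A/π) against 0.6 μm
(strictly below → punctum); MLE/2 is available as an alternative radius
definition (`radius_mode: feret`). Filament requires E strictly greater
than 11 μm; the boundary values themselves fall to rod and swollen
respectively. All thresholds live in the run config.

## Reporting

Per cell: class counts, count-based percentages (and area-weighted
percentages as extra columns, since the denominator convention is a
choice), and the (E, A) records of every filament and rod. A cell with
zero retained objects reports *undefined* percentages, not zeros, and is
excluded (with a warning) from group statistics. Groups aggregate at the
cell level — unweighted mean ± sd of per-cell percentages — not by
pooling objects, so large cells do not dominate.

## Synthetic scenes and what they show

`SceneSpec` renders one cell-like field: filaments and rods as
constant-width tubes (0.5 μm) stamped along curvature-bounded random
walks, puncta and swollen as discs, with per-object brightness jitter
(0.7–1.3×), Gaussian optical blur (σ = 0.08 μm), a long-wavelength haze
field, Poisson shot noise and additive read noise (sd 5 on a background
of 100 and object amplitude ~500). Placement enforces a minimum
spacing (1 μm) by rejection sampling; infeasible packings raise an
error naming the class. Identical specs (including the seed) produce
bit-identical scenes.

Planted tube lengths are drawn in the same (1, √2) chamfer metric the
skeleton geodesic uses — a tube at 22.5° has a lattice geodesic up to
8% longer than its Euclidean arc length, so planting Euclidean lengths
would bias the ground truth itself. Planted class geometry must keep a
guard margin (default 10%) away from the 11 μm and 0.6 μm rule
thresholds; in addition, the default punctum (0.2–0.4 μm) and swollen
(0.8–1.2 μm) radius ranges allow for the ~+0.15 μm support bias that
thresholding a PSF-blurred edge introduces into measured equivalent
radii.

What passing synthetic tests shows: the measurement conventions are
internally consistent (oracle equivalence), the classifier switches at
exactly the configured thresholds, and the full pipeline recovers a
planted 30/30/30/10 class mix within a few percentage points at
realistic SNR. What they do not show: robustness to real-image
phenomena the generator omits — Z-projection overlap of crossing
structures, touching/merging organelles (no watershed splitting is
attempted), spatially varying focus, photobleaching, and camera
artefacts beyond Poisson + Gaussian noise. Percentages on real data also
depend on the manual cell outlines.

## Numerical choices and degenerate inputs

μm→px conversions round to the nearest integer pixel (minimum 1) where
an integer kernel is required. Constant images: background subtraction
returns zero, enhancement returns zero, thresholding raises (degenerate
histogram). Empty cell regions and anisotropic pixel calibrations are
rejected with explicit errors. The analysis path contains no randomness:
rerunning a batch with identical config and inputs reproduces
byte-identical CSVs. Float accumulation in geodesic sums can land an
object measured at exactly the 11 μm boundary on either side of the
strict comparison; the boundary sweeps therefore locate the switch to
within one sweep step.

## Problem sizes

The bundled validation uses scenes of 420–512 px square at 0.1 μm/px
with 10–20 planted objects per scene and five scenes per recovery
experiment; the boundary sweeps use 101 tube lengths and 51 disc radii.
These sizes keep the full suite fast while leaving every object large
enough (≥ 4 px) for its class geometry to be unambiguous.
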