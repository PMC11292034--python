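# Methods

This note documents the models, conventions, defaults and numerical
choices behind `panicletraits`, and what the synthetic benchmark does
and does not demonstrate about real panicle images.

## Scale calibration

A red disk of known physical radius (default 25 mm) anchors the image
scale. Red pixels are classified in HSV — hue ≤ 10° or ≥ 350°,
saturation ≥ 0.4, value ≥ 0.2, all configurable — and the largest
connected red component above a minimum area (200 px²) is taken as the
calibrator. Its radius is that of the equal-area circle,
`sqrt(area/π)`, rather than half a bounding-box side: the equal-area
radius is insensitive to a ragged segmentation boundary, whereas a
bounding box inherits the single worst protrusion. A second red
component within 20 % of the largest's area raises an "ambiguous
calibrator" error rather than silently guessing. The pel density is
`mm_per_pixel = real_radius_mm / pixel_radius`; every downstream
millimetre quantity is a pixel quantity times this factor, which is
what makes the pipeline camera-distance-free (and is exercised by the
scale-invariance tests: measurements in mm are stable under 2× image
rescaling to within digitisation error).

Coordinates are 0-based `(row, col)`; boxes are half-open
`[min, max)`, so a box's area is exactly the number of pixels it
covers when its corners are integers.

## Grain counting and the panicle morphology index

The PMI is `1 − |N_actual − N_forecast| / N_actual`, clamped to
[0, 1]: the printed expression can go negative when a detector
over-forecasts beyond twice the true count, but the index is defined
on [0, 1], so the clamp is applied at construction. Count calibration
divides the raw detector count by the PMI and rounds half-up to an
integer (grain counts are integers). The divisor is floored at 0.002
— strictly below the smallest ground-truth PMI a panicle of up to 500
grains can produce — so the floor only ever catches the degenerate
PMI = 0 case and never disturbs the exact undercount-recovery
identity: for any `n_forecast ≤ n_actual`, PMI equals
`n_forecast/n_actual` and calibration returns `n_actual` exactly.
The floor is configurable for users who prefer a more conservative
cap on the amplification of very small counts.

PMI values enter the pipeline through a provider contract
(`image_id → PMI`): ground-truth count pairs, an external CSV
(typically the output of a trained image-regression model), or a
geometric heuristic — one minus the overlapping fraction of total
detection-box area, with the union area computed exactly on box
polygons. The heuristic is a desk-scale stand-in with the right
qualitative behaviour (1.0 for disjoint boxes, decreasing with
stacking); it is not a substitute for a trained regressor on real
images, where occlusion is not fully visible in the surviving boxes.

## Grain morphometry

Screening keeps grains that are unoccluded or nearly so: greedy NMS at
IoU 0.8 over the detector output, then a confidence floor of 0.7 —
the combination that performed best for grain length and aspect ratio
in the source experiments — with crops taken at the original box size
(no padding) by default; 2-px padding is available. The IoU threshold
is interpreted as the NMS threshold applied to detector output: at
inference time there are no ground-truth boxes to compare against, so
a predicted-vs-actual reading is not executable. An optional pairwise
overlap filter (`max_pairwise_iou`, off by default) additionally drops
surviving boxes that still overlap each other.

Each crop is thresholded (Otsu on the grey level by default; the side
of the threshold that dominates the crop border is taken as
background, so both bright-on-dark and dark-on-bright grains work) and
particle filtering keeps the largest connected component as the grain
body. The minimum-area rotated rectangle is computed by rotating
calipers over the convex hull of the foreground pixels' unit-square
corners: a `w × h` axis-aligned block therefore measures exactly
`(w, h)` (a pixel-centre convention would give `(w−1, h−1)`). The
longer side is grain length, the shorter grain width; the angle of the
length axis is reported in degrees [0, 180). Panicle-level traits are
arithmetic means over measured grains, with mean aspect the mean of
per-grain ratios (not the ratio of means — the two differ whenever
grain size varies, and the per-grain mean weights every grain
equally).

Grains whose crop fails segmentation are skipped and logged; a panicle
with zero measurable grains is an explicit error, not a silent zero.

## Panicle length

Segmentation thresholds the HSV saturation channel (Otsu by default) —
the board is grey and unsaturated, plant tissue is not. The red
calibrator is as saturated as the plant, so calibrator-coloured pixels
are excluded from the foreground before cleaning; small-area removal
then clears noise, holes are filled, and the largest remaining
component is kept (one panicle per image by protocol). The small-area
floor defaults to 100 px² at a 3000×4000 reference resolution and
scales with image area.

The cleaned mask is thinned to a 1-px-wide, 8-connected skeleton
(topology-preserving thinning via scikit-image). Endpoints are
skeleton pixels with exactly one foreground 8-neighbour. The main path
starts at the bottom-most endpoint (maximum row; ties to the smaller
column) and, following the "top 20" rule, takes the up-to-20 endpoints
of minimum row as candidates; "top" is read spatially, as nearest the
image top. A* computes the shortest path to each reachable candidate
with unit cost per move — diagonals included — so the optimised
quantity is the pixel count, which is exactly the quantity the method
reports; the Chebyshev-distance heuristic is admissible under unit
cost, so A* is exact (and is tested for exact agreement with BFS).
Among the candidate paths, the one with the greatest pixel count is
the main path. Length is `pixel_count × mm_per_pixel` by default; an
alternative `euclidean_steps` mode sums per-step lengths (1 or √2),
since raw pixel count systematically underestimates diagonal runs by
up to √2. Ties in A* are broken by a fixed neighbour scan order
(N, NE, E, SE, S, SW, W, NW) and insertion order, so results are
deterministic.

## Baseline detector

The classical detector exists so the pipeline runs end to end without
trained weights: foreground threshold → connected components →
components larger than 1.6× the median area are split by
distance-transform watershed → one box per component, with confidence
= the component's solidity (clean single grains are nearly convex;
merged or fragmentary blobs score lower, which gives the confidence
screen something real to act on). The default foreground rule is an
HSV hue band tuned to grain colour (20°–75°, s ≥ 0.25, v ≥ 0.35):
in a full scene the stem and the calibrator are as bright as the
grains, so a global intensity threshold (the `otsu_value` option)
cannot isolate grains and is offered only for grain-on-plain-board
crops; a fixed `rgb_range` rule is also available. This detector is a
classical baseline, adequate on high-contrast scenes; real panicle
images need a trained detector supplied through the detection-file
interface.

## Synthetic scenes

Scenes emulate the acquisition protocol at its native scale: default
2000×1500 px with a 250-px calibrator radius, i.e. 0.1 mm/px — the
scale a 3000×4000 smartphone image of a board at ~35 cm works out to.
Content: a grey board (RGB 205/205/208) with Gaussian sensor noise
(σ = 2), the red calibrator disk, a quadratic-Bezier main stem
(7 px thick) with 5 short upward branches, and 50 elliptical grains of
9.0 × 3.0 mm (SD 0.25/0.12 mm, the scale of within-panicle variation
in cultivated rice), anti-aliased by 2×2 supersampling, placed in a
band around the stem. `overlap_level` is the probability that each
grain is placed against an already-placed grain rather than in free
space; at level 0 all bounding boxes are pairwise disjoint by
construction. Randomness flows from the scene seed through four
independent substreams (stem shape, grain sizes, placement, pixel
noise), and stem control points and branch parameters are drawn as
resolution-free fractions, so `SceneSpec.scaled(k)` renders the same
physical scene at k× resolution — the basis of the scale-invariance
tests.

Ground truth records every grain's oriented ellipse and axis-aligned
box, the stem polyline, and the pixel count of the skeletonised
stem-only raster (the reference for panicle-length recovery), plus
the implied mm/px.

The detection error model makes each grain's miss probability grow
with its occlusion `o` (its maximum box-IoU with any other grain):
linearly, `p_miss = α·o` with α = 0.9 by default (a logistic variant
is available), with Gaussian corner jitter (σ = 1 px) and confidences
drawn around `0.92 − 0.35·o`. The linear form is chosen for
analysability: the expected miss count is `Σ α·o_i`, which the tests
check against simulation.

**What the synthetic benchmark does not show.** Scenes are stylised:
grains do not touch the stem (so connected components are
well-defined for the classical detector), there are no awns, shadows,
specular highlights or field backgrounds, grain colour is uniform,
and occlusion is simulated at the box level rather than rendered as
true 3-D overlap. Passing the recovery tests therefore demonstrates
the correctness of the measurement algorithms (calibration,
screening, min-rect, skeleton path search, count calibration) under
known geometry — not the accuracy of any detector or PMI regressor on
real images, which depends on trained models outside this package's
scope.

## Problem sizes and the reproduction script

`scripts/acceptance.py` regenerates its numbers from scratch at a
given seed: 50 scenes per overlap level (0.2/0.4/0.6) for the
counting experiment — scene truth is generated without rendering,
since counting never looks at pixels — 8 rendered zero-overlap scenes
for morphometry and detector mAP50, 8 rendered stem scenes for
panicle length, the full 125,250-pair undercount-recovery sweep, and
100 random-skeleton A*-vs-BFS comparisons. With ground-truth PMI and
a miss-only error model, calibrated counting is exact (MAPE 0); on
real images the PMI itself is predicted and the residual calibrated
error is dominated by PMI prediction error, so the raw-vs-calibrated
gap, not the absolute zero, is the meaningful output. All
randomness derives from `--seed`; a rerun with the same seed is
byte-identical.

## Known limitations

* The PMI heuristic sees only surviving boxes; fully hidden grains
  leave no box evidence, so it overestimates PMI on severely occluded
  panicles — exactly the regime where a trained image regressor is
  needed.
* Pixel-count path length under-measures diagonal stem segments (up
  to √2); the `euclidean_steps` mode corrects this but then the
  measured quantity is no longer literally "number of pixels".
* Single calibrator, no lens-distortion or perspective correction;
  the scale is assumed uniform across the frame.
* One panicle per image is assumed (largest-component retention).
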