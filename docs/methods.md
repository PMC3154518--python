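# Methods

This note records the models implemented in `vertascan`, the assumptions
behind them, the synthetic study conditions used for testing, and the
numerical choices made where the underlying methods leave the design open.

## Problem setting

Cervical-spine mobility analysis needs accurate contours of the vertebral
bodies C3–C7 on lateral radiographs in flexion, neutral and extension.
The films are low-contrast with blended bone contours, and the spine
curvature changes so much across the three positions that a global
multi-vertebra shape model cannot segment individual bodies well.  The
package therefore uses one local Active Shape Model (ASM) per vertebra.
A local model only works if it starts close to its target, so the bulk of
the pipeline is a semi-automatic initialization: the user marks two
points (upper anterior corner of C3, lower anterior corner of C7) and the
pipeline finds all ten anterior corners from them.

## Stage models

### Contrast-limited adaptive histogram equalization

The image is divided into `tiles_y × tiles_x` contextual regions (default
8×8).  Each region's 256-bin histogram is clipped at
`clip_limit · n_pixels / n_bins` (default clip factor 2.0); the clipped
excess is redistributed uniformly, and a single second pass re-caps bins
the redistribution pushed back over the ceiling.  The region mapping is
the clipped CDF scaled to the full bit-depth range, hence monotone.  At
each pixel the four surrounding region-center mappings are blended
bilinearly; in the border band outside the rectangle of region centers
the blend degenerates to edge-linear and corner-nearest interpolation
(implemented by clamping neighbor indices).  Clipping bounds the contrast
gain in homogeneous areas and thus the noise amplification.

### Edge detection

Classic Canny: convolution with the sampled, unit-sum 2-D Gaussian
(truncation radius ⌈3σ⌉, reflective padding; default σ = 1.4 px), Sobel
3×3 masks applied as correlation, magnitude `√(Gx²+Gy²)`, direction from
the two-argument arctangent.  Non-maxima suppression quantizes the
direction to {0°, 45°, 90°, 135°} and keeps a pixel iff its magnitude is
≥ both neighbors along that direction; the 1-px image border is zeroed.
Hysteresis accepts pixels above the high threshold and grows through
pixels in `[low, high]` under 8-connectivity (4 available).  Thresholds
are absolute by default (10/25 on 8-bit magnitudes) — on these images the
population of NMS-positive pixels is dominated by near-zero plateau
responses from noise and the illumination ramp (the ≥ rule keeps
constant-gradient plateaus), which makes mid-range quantiles
uninformative; a quantile mode remains available.

A recursive smoothing backend implements Deriche's fourth-order
exponential-trigonometric approximation of the Gaussian.  The four poles
give the recursion denominator; the causal numerator is fitted to the
first four impulse-response samples, the anticausal numerator follows
from symmetry, and the pair is normalized to unit DC gain.  Its cost is
independent of σ and it agrees with the FIR kernel to well under 1% RMS
(tested at σ = 1, 1.4, 3).

### Contour tracing

The binary edge map is converted to ordered 8-connected chains by greedy
bidirectional walks with visited marking.  Three details matter on real
NMS output:

- **Junctions** are pixels whose 8-neighborhood splits into ≥ 3 connected
  runs (crossing number), not pixels of degree > 2 — NMS regularly leaves
  paired pixels along near-diagonal edges, and a degree test would break
  chains in the middle of smooth contours.
- **Walks extend in both directions** from their seed, so a chain never
  breaks at the arbitrary pixel the scan happened to start from (for
  loops, that pixel is the topmost one — often precisely a corner).
- **Fragment merging**: chains whose loose ends lie within 3 px are
  spliced back together, nearest pair first; junction cuts land on looped
  edges, frequently at the very corners the next stage must find.  A long
  chain whose end gap is small relative to its length counts as closed.

Optional skeletal thinning before tracing exists but is off by default —
it nibbles corner apexes, biasing the corner detector by 1–2 px.

### Corner detection

Each contour is simplified with the exact recursive Douglas–Peucker rule
(iterative implementation; ties for the farthest point go to the lowest
index; closed contours are split at their two mutually farthest points
first).  Interior vertices with a turning angle in [30°, 150°] are the
corners (near-collinear vertices and hairpin artifacts are rejected).
The default ε = 4 px.  Corner localization on rasterized chains carries
an intrinsic error floor of roughly 1–3 px: the blurred edge retreats
from a true corner apex, the chain is quantized to the pixel grid, and
the farthest-point vertex can sit one or two staircase steps from the
apex.  On crisp noise-free fixtures the worst case measures ≈ 2.2–2.8 px;
noise barely changes the distribution.

### Vertebra localization

The spine-curvature model is the Procrustes mean of anterior-corner
landmark sequences (10 landmarks: upper and lower anterior corner of each
body, strictly ordered top to bottom), stored gauge-fixed: centroid at
the origin, unit centroid size, first-to-last chord along +y.  The unique
orientation-preserving two-point similarity maps its first landmark onto
the top click and its last onto the bottom click, exactly.  Matching
walks the landmarks top to bottom; candidates are unused corners whose
projection on the click axis is not above the last matched corner
(preventing upper/lower corner swaps between adjacent bodies), and the
nearest within the search radius wins.  The module default radius is 25%
of the inter-click spacing (≈ 10 px at desk scale); the pipeline config
passes 20 px because the positioned model's mid-spine deviation under
realistic curvature variability exceeds the quarter-spacing radius
(measured on validation fixtures).  Unmatched landmarks keep their
model-predicted position.  Merged vertebrae (no corner between two
bodies) remain an acknowledged failure mode with no mitigation.

### Statistical shape model

Generalized Procrustes alignment (pair fits by the complex-regression
closed form, reflections disallowed; set alignment iterates against the
gauge-fixed mean until it moves < 1e-8 RMS) followed by PCA of the
aligned 2n-vectors.  The model keeps the smallest number of modes
reaching 95% of total variance; eigenvalues below (1e-9 × coordinate
scale)² are treated as zero so degenerate training sets yield zero-mode
models.  Generated shapes are `pose(x̄ + P b)`; projection alternates the
Procrustes pose fit with the tangent projection `b = Pᵀ(pose⁻¹(x) − x̄)`
until `b` stabilizes (exact on shapes generated from in-range
parameters), then clamps `b` to ±3√λ per mode — the conventional
allowable-region constraint.

### ASM search

The grey-level model at each landmark is the mean and covariance of
normalized profiles of `|dI/dn|` (central differences of bilinearly
interpolated intensity) sampled at unit steps along the landmark normal,
profile length 2k+1 with k = 6.  Normals are perpendicular to the chord
between the landmark's neighbors, shape treated as closed.  Covariances
get a ridge `δI`, `δ = 1e-6 · trace / (2k+1)`, keeping them invertible
even for near-identical training profiles.  During search each landmark
evaluates `2·search_range+1` candidates along its normal (default ±4 px,
ordered by |offset| so cost ties keep the smallest move), takes the
Mahalanobis-nearest, and the proposed cloud is regularized through the
shape model (pose refit + clamped b).  Iteration stops when the mean
landmark movement drops below 0.5 px, when a step fails to improve the
total profile cost (the step is rejected), or at 50 iterations.  No
multi-resolution pyramid is used.  The fit is deterministic given image,
initialization and models.

### Evaluation

Point-to-line distance: for each gold landmark, the minimum distance to
the natural cubic spline through the fitted landmarks, parameterized by
cumulative chord length; the minimum is found by dense sampling (1000
points per landmark interval) plus bounded local refinement, accurate to
well under 1e-3 px against a 10⁴-point oracle.  Success/failure
decomposition trims iteratively: cases above mean + 3 SD (ddof = 1) of
the current success set move to the failure set until a fixed point; a
zero-spread sample has no failures.  On 51-case batches the failure rate
is by construction a multiple of 100/51 ≈ 1.96%.  Pixel↔mm conversion is
`px · 25.4 / dpi`; at the 146 dpi scan resolution 1 px = 0.174 mm,
i.e. roughly 0.2 mm.

## Synthetic study conditions

The generator emulates the relevant properties of digitized cervical
film — low contrast, blended contours, smooth illumination drift,
stochastic geometry — without claiming photorealism.  Defaults, chosen
once as a realistic desk-scale regime and used by all tests:

| parameter | default | meaning |
|---|---|---|
| image_size | 512×512 px | desk-scale frame (full film scale 1763×1755 available) |
| n_vertebrae | 5 | C3–C7 |
| curvature | 35 px | lateral half-sine bow of the spine axis |
| vertebra_size | 88×48 px | body width × height before jitter |
| intensity_contrast | 45 grey levels | body vs. 80-level background |
| boundary_blur | 1.5 px | Gaussian blur of the rendered frame ("blended contours") |
| noise_sd | 3 grey levels | additive Gaussian noise |
| illumination_gradient | 25 levels | diagonal ramp amplitude |
| corner_radius | 2 px | rounded body corners (0 = plain polygons) |
| shape_jitter / size_jitter | 2.5 px / 5% | per-corner and per-body variability |

Bodies are convex quadrilaterals rotated to the local axis tangent, with
12 ASM landmarks (corners + 2 per side; indices 0 and 9 are the anterior
corners).  Rendering is deterministic per seed; the noise stream is
independent of the geometry stream so noise levels can change without
moving the geometry.

What the generator does **not** emulate — overlapping anatomy (mandible,
shoulders), radiographic speckle/Poisson noise, merged vertebrae, grid
artifacts — bounds what passing tests show: they validate the algorithms
against exact ground truth under controlled degradation, not clinical
performance.  In particular the profile models trained on synthetic
renders are much cleaner than real bone/soft-tissue profiles.

## Problem sizes used in tests and the acceptance script

Model training uses 8 rendered spines (40 vertebra shapes) and a
30-sample curvature-model set; shape-model recovery uses 200 sampled
shapes; the ASM improvement experiment uses 20 clean single-vertebra
fixtures with initializations perturbed up to 5 px; localization accuracy
aggregates 10 default-noise spines (100 anterior corners); the error-table
demonstration segments a 51-case batch, matching the reporting granularity
of a 51-film study.  These sizes make the full suite run in ~30 s and the
acceptance script in ~20 s on one CPU while keeping every statistical
check well-powered.

## Known limitations

- Corner localization cannot beat the ~1–3 px discretization floor
  described above; at a 3-px tolerance roughly 90% of anterior corners
  match at default noise, and the matcher (not the model placement) is no
  longer the binding constraint.
- The eigenvalue-recovery check compares against the variance the
  generator realized in the drawn sample; the nominal spectrum can only be
  matched to within its own ~√(2/n) sampling spread.
- C3, adjacent to the upper image margin, shows the largest segmentation
  errors — the profile search has less uncluttered gradient context there,
  echoing the behavior of automated initialization on real film.
- The two-click ROI requirement is inherent to the method; fully automatic
  ROI detection is out of scope.
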