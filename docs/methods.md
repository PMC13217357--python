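# Methods

This note documents the models and numerical choices behind `dpetrack`:
what each stage computes, which parameters matter, what the synthetic data
emulate, and where the design was genuinely open.

## Geometry conventions

Contours are closed polygons of sub-pixel `(x, y)` vertices in image
coordinates (origin top-left, y down), stored with positive shoelace area
("counter-clockwise" under this module's sign convention). Morphometry is
standard:

- circularity = 4·π·A / P² (isoperimetric ratio, 1 for a disk);
- aspect ratio = minor/major side of the minimum-area rotated bounding
  rectangle, in (0, 1];
- polygon IoU by exact clipping (shapely), not rasterisation.

Two pairwise similarities feed the tracker. Both are bounded in [0, 1] and
translation-invariant:

- **contour similarity** `1 − d_H/(d_H + D)`, with `d_H` the symmetric
  Hausdorff distance between centroid-aligned boundaries (densified, so
  the value does not depend on where the vertex list starts) and `D` the
  geometric mean of the two major-axis lengths. The geometric mean was
  chosen over the arithmetic mean so that a compact cell versus a long
  sliver scores below 0.5: the arithmetic mean is dominated by the longer
  axis and saturates the score.
- **shape similarity**: sum of three bounded terms — area ratio
  min/max, aspect-ratio agreement `1 − |r₁ − r₂|`, and contour
  similarity — so identical (translated) shapes score exactly 3.

Whether contour similarity should be computed before or after alignment is
open; we align by centroid (translation only, no rotation), because
cross-frame matching should tolerate motion but still penalise rotation
of elongated cells slightly less than genuine shape change would be
penalised. Computing it unaligned would conflate displacement with shape
difference and duplicate what IoU already measures.

Arc-length resampling iterates the equal-spacing pass to its fixed point
(all chords equal, vertex 0 pinned), making resampling idempotent at a
given vertex count.

Chain codes use the Freeman 8-direction alphabet (0 = east, advancing
counter-clockwise on screen); encoding a closed 8-connected pixel path and
decoding are exact inverses. Boundary pixel paths come from Moore-neighbour
tracing of the instance mask.

## FT-KAN backbone

Following the Kolmogorov–Arnold design, each (input, output) connection of
an FT-KAN convolution carries a learnable univariate function — a
truncated Fourier series

    φ(x) = Σ_{k=1..G} a_k cos(k·s·x) + b_k sin(k·s·x)

with G harmonics (default 3) and input scale `s` (default π, mapping
tanh-normalised features into [−π, π]). A plain two-stride convolutional
stem (two 3×3 stride-2 convolutions with ReLU) precedes the FT-KAN blocks;
residual FT-KAN blocks act at strides 4 and 8 and a further stride-2
convolution yields the stride-16 level. Default widths are 16/32/64
channels — small enough that a 256×256 frame runs in well under two
seconds on one CPU core and that reduced-scale training fits a desk
budget. Normalisation layers are omitted at these widths; Adam handles
the conditioning, and their absence keeps the stem exactly
shift-equivariant, which the tests exploit.

All trainable components run on a compact reverse-mode autodiff layer
(`dpetrack.nn`) written for this package: float64, single-threaded,
operations limited to what the models need (broadcast arithmetic, matmul,
trigonometric/sigmoid nonlinearities, patch extraction, bilinear map
sampling). Training is therefore bitwise reproducible for a fixed seed.

## Segmentation pipeline

1. **Detection.** A centre-heatmap head and a log-size head (3×3
   convolutions) read the stride-4 features concatenated with a 4×4
   average-pooled intensity channel. The intensity shortcut is an
   architectural choice: cells are intensity blobs, and the skip lets the
   centre heat train within tens of epochs. Decoding is peak-local-max at
   a score threshold followed by greedy NMS on boxes (IoU 0.5).
2. **Initial contour.** An ellipse inscribed in the detected box with N
   equally-angled vertices (N = 128 by default).
3. **BFE offsets.** Per vertex, the bilinearly sampled stride-4 feature
   vector is concatenated with a one-hot Freeman direction of the
   discretised contour at that vertex; a two-layer head predicts a 2-D
   offset bounded by `tanh · r_max` (r_max = 4 px).
4. **MLP refinement.** A circular window (previous/self/next vertex
   features plus normalised position) feeds a shared MLP predicting
   bounded offsets; the pass can be repeated. Both offset heads have
   zero-initialised output layers, so an untrained (or ablated) model is
   exactly the identity on the contour.
5. **Dynamic Profile Evolution.** Landmarks are extracted classically:
   skeleton endpoints of the instance mask, each extended radially to the
   last mask pixel (placing the landmark on the protrusion tip rather
   than inside the taper), plus local maxima of gradient-magnitude
   saliency along the contour; a flat patch falls back to the contour
   vertices. Each iteration every vertex moves along its outward normal
   by an adaptive step combining region evidence (outward while the
   vertex samples interior-like intensity, inward over background, using
   an interior/background threshold estimated from the initial mask) and
   attraction to the nearest landmark within a 6 px capture radius
   weighted by saliency. Per-vertex steps halve when their region force
   flips sign (a bisection onto the boundary), anneal globally by 0.985
   per iteration, and the mean displacement is capped to be non-increasing
   (a trust-region-style limit), so the displacement log is monotone by
   construction. Vertices are redistributed by arc length every 8
   iterations so concavities stay covered; light curvature smoothing is
   applied only near the boundary and never to landmark-captured
   vertices. The loop stops when mean displacement < 0.05 px or after 50
   iterations. Self-intersections are repaired by reprojection onto a
   smoothed version of the contour (convex hull as a last resort). The
   energy the evolution descends is not prescribed anywhere; this
   attraction-plus-region rule is an explicit, documented stand-in with
   the stated convergence behaviour.
6. **Postprocessing.** Circular moving-average smoothing (window 5),
   minimum-area filtering (30 px²) and IoU-based deduplication keeping
   the higher score.

**Training (reduced scale).** Loss = penalty-reduced focal loss on the
centre heatmap + L1 on log box sizes at GT centres + smooth-L1 (a
Charbonnier surrogate, smooth everywhere) on vertex positions against
arc-length-resampled GT polygons, cyclically aligned by the angle of the
first ellipse vertex from the GT centroid. Contour heads are seeded from
GT boxes during training (teacher forcing); GT is matched to detections by
Hungarian assignment on centre distance. Dropout (p = 0.1) acts on the
offset-head hidden layers. The learning-rate schedule is exponential step
decay `L_{i+1} = L_i·γ`; the full-scale reference schedule is L0 = 1e-5
with γ = 0.1 every 50 epochs over 200 epochs, while the desk-scale runs in
the tests use L0 = 3e-3, γ = 0.5 every 10 epochs for 30 epochs over 200
synthetic 128×128 frames with 5 cells each — sizes chosen so a full
training fits in a few minutes on one core while still reaching AP₅₀ ≥ 0.5
on held-out frames.

## Tracking

Consecutive frames form a bipartite graph over the Top-K scored instances.
Edge features initialise from the fully connected map of the three pair
similarities `e⁰ᵢⱼ = f(IoU, cosine, contour)`; the two directions are
distinct features distinguished by learned direction embeddings. Message
passing updates every directional edge by
`eᵗᵢⱼ = f_e(e⁰ᵢⱼ, eᵗ⁻¹ᵢⱼ, vᵢᵗ⁻¹, vⱼᵗ, MhDᵢⱼ, shapeᵢⱼ)` with a tanh squash,
and every node by a learned map of the sum of its incident edge features
(the node-update rule is not prescribed; learned-map-then-sum is our
choice). T = 3 rounds by default. Edge confidence is the sigmoid of a
linear read-out, averaged over the two directions; matching maximises
total confidence over edges above S_τ (default 0.5) by optimal assignment.
The threshold rule alone would permit many-to-one matches; optimal
assignment on the thresholded scores is the documented resolution, and the
tests verify it equals exhaustive search on small graphs.

The Mahalanobis quadratic form defaults to the **inverse** empirical
covariance of the pooled node features (the standard Mahalanobis
distance); the configuration switch `mhd_matrix: literal_sigma` instead
places the covariance itself between the difference vectors for strict
fidelity to the printed form. The discrepancy is documented, not silently
fixed.

Candidate edges are gated by centroid distance (3× mean cell diameter), T
rounds and S_τ are configuration-exposed, and Top-K is applied per frame.
Unmatched previous-frame cells become occluded, re-entering later graphs
with their last-seen features for up to `max_gap` = 3 frames (no motion
extrapolation by default) before terminating; track ids are never reused.

Node features ("appearance") are the mean stride-4 backbone feature along
the contour when an image is available, or an 8-dimensional geometric
descriptor (area, perimeter, circularity, aspect ratio, rotated-rectangle
sides, radial mean/spread) for detection streams without pixels. Tracker
training minimises binary cross-entropy of the edge confidence against
same-identity labels from ground-truth correspondences; the toy corpus is
20 short synthetic sequences (6 cells, 8 frames, 10% drops) for 30 epochs.

## Evaluation metrics

Detection follows COCO: greedy score-ordered matching per IoU threshold,
101-point interpolated AP, AR as mean best recall over thresholds
0.50:0.05:0.95, and area classes small < 32², mid 32²–96², large > 96² px²
(the cutoffs are the COCO convention; the source material names the
classes without defining them). Tracking follows CLEAR-MOT with
correspondence persistence: previous matches are kept while still valid
(IoU ≥ 0.5 for polygons, centroid distance for point tracks), the
remainder is matched by Hungarian assignment, MOTA = 1 − (FN+FP+IDS)/GT,
identity switches count ground-truth reassignments, and IDF1 comes from a
global optimal identity assignment on co-occurrence counts.

## Synthetic data

The generator emulates adherent neuronal/microglial cultures imaged by
low-contrast shadow microscopy at 10-minute intervals over 20 h (121
frames per sequence, the default acquisition model):

- **Shapes**: ellipse (area-preserving eccentricity 0.55–0.9, body radius
  10 ± 1.5 px) plus 2–5 Gaussian radial spikes (length 4–10 px, angular
  width 0.22 rad, apices ≥ 3 widths apart so each tip is a genuine local
  maximum of radial distance). With a 1 μm/px pixel size this yields
  perimeters around 95 ± 14, areas around 490 ± 130, circularities around
  0.67 ± 0.08 and aspect ratios around 0.78 ± 0.14 — mildly elongated,
  protrusion-bearing cells in the size regime of adherent
  hippocampal-line cultures. Real populations of this kind are reported
  with stronger elongation (modal aspect ratios near 0.45); the defaults
  favour milder eccentricity because strongly elongated bodies at this
  small pixel scale render with ambiguous thin midsections that no
  boundary evidence can recover, which would conflate generator artefacts
  with method errors. Shapes are rigid per cell; real cells
  remodel continuously, so appearance-based matching is easier here than
  in real data (see Limitations).
- **Motion**: persistent random walk — heading turn ~ N(0, 0.6 rad),
  step ~ Gamma(2, 1.25 px) per 10-minute frame, reflected at the field
  margins. The "stress" condition multiplies step length by a motility
  factor (< 1), mirroring oxidative-stress motility reduction
  qualitatively; distribution parameters are configuration, not claims
  about real cells.
- **Occlusion**: detection drops (probability per cell-frame, runs of at
  most `max_consecutive_drops`, always followed by a visible frame) and,
  optionally, steered overlap events in which paired cells pass within a
  diameter of each other.
- **Rendering**: filled polygons (intensity 0.35 on background 0.75), 1 px
  Gaussian edge blur, additive Gaussian noise (σ = 0.02), 8-bit frames.
  This mimics low-contrast shadow imaging; it does not model lensless
  optics, photobleaching, or cell division.

Everything is bit-exact for a fixed (config, seed); the global seed fans
out to per-module generators via fixed offsets.

## What passing tests do and do not show

The tests demonstrate internal correctness (oracle equivalence for
geometry, matching and metrics), convergence behaviour of the contour
evolution, and that the learning components actually learn (detection to
AP₅₀ ≥ 0.5, edge classification to ≥ 95% at desk scale). Because the
synthetic cells are rigid, high-contrast and free of division, these
results bound the method's behaviour under ideal conditions only; real
recordings with ambiguous boundaries, shape remodelling and touching cells
will be strictly harder, and the benchmark numbers here are not
comparable to measurements on real data sets.

## Known limitations

- The spline-basis KAN convolution variant is not implemented (Fourier
  basis only), and there is no ImageNet-style pretraining.
- The landmark extractor is classical (skeleton + gradient saliency), not
  learned; the placement of FT-KAN blocks relative to the stem and the
  mechanism of receptive-field adaptation are design choices documented
  above, since no prescription exists.
- Holes and multi-polygon instances, 3-D geometry and lineage (division)
  are out of scope.
- CLEAR-MOT here uses IoU/centroid gating without fragmentations or
  mostly-tracked/mostly-lost summaries; HOTA is not implemented.
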