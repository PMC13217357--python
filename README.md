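# dpetrack

Contour-based cell segmentation, occlusion-robust multi-object tracking
and migration quantification for grayscale time-lapse microscopy.

Long-term live-cell recordings of adherent cultures (hippocampal neuronal
lines, microglia) pose two coupled problems: delineating each cell's full
extent — including thin protrusions — despite low contrast and shape
variability, and keeping each cell's identity across hundreds of frames
despite partial occlusion and detection dropouts. `dpetrack` implements a
dynamic-contour-evolution pipeline for both, plus the downstream
morphometry and trajectory analytics, and a synthetic time-lapse generator
with complete ground truth that drives every test.

## The method in brief

**Segmentation.** A small convolutional backbone with Fourier-KAN
adaptive kernels — each weight is a learnable truncated Fourier series
φ(x) = Σₖ aₖ cos(k·s·x) + bₖ sin(k·s·x) — feeds a centre-heatmap detector.
Each detection starts as an ellipse inscribed in its box; a
Boundary-Feature-Enhancement head predicts per-vertex offsets from sampled
features and the local Freeman chain-code direction; an MLP head refines
the whole vertex sequence; and Dynamic Profile Evolution (DPE) iteratively
stretches or contracts vertices along their normals toward extracted
cellular landmarks (protrusion tips, boundary-saliency ridges) until the
mean displacement falls below tolerance. Smoothing, noise removal and
deduplication finish the instance set.

**Tracking.** Instances of consecutive frames form a bipartite graph.
Edges initialise from e⁰ᵢⱼ = f(IoUᵢⱼ, Simᵢⱼ, Contourᵢⱼ) — polygon overlap,
appearance cosine similarity, contour-shape similarity — and a
similarity-boosted GNN updates them with
eᵗᵢⱼ = f_e(e⁰ᵢⱼ, eᵗ⁻¹ᵢⱼ, vᵢᵗ⁻¹, vⱼᵗ, MhDᵢⱼ, shapeᵢⱼ), where MhD is the
Mahalanobis distance between node features. An edge-confidence head
yields S_sim per pair; pairs with S_sim > S_τ are matched one-to-one by
optimal assignment, and unmatched cells survive as occluded for up to
`max_gap` frames, preserving identities across gaps.

**Quantification.** Per-cell perimeter, area, circularity (4πA/P²) and
aspect ratio (min/max side of the minimum-area rotated rectangle) in
physical units; origin-normalised trajectories; cumulative path lengths;
cohort comparisons (e.g. stress vs control motility).

Everything trainable runs on a compact numpy autodiff layer — no GPU or
deep-learning framework required — and is bitwise reproducible per seed.

## Worked example

```python
import numpy as np
from dpetrack import simulate, tracker, metrics

# 20 cells, 50 frames at 10-min intervals, 10% detection drops
cfg = simulate.SceneConfig(n_cells=20, duration=490, frame_interval=10,
                           drop_prob=0.10, seed=0)
stack, gt = simulate.simulate_sequence(cfg)
dets, _ = simulate.inject_occlusion(gt, cfg, np.random.default_rng(0))

net, _ = tracker.train_toy_tracker(seed=0)          # ~15 s on one core
tracks = tracker.link_tracks(dets, net=net)

gt_frames = {t: dict(gt.polygons[t]) for t in range(gt.n_frames)}
ev = metrics.clear_mot(tracks, gt_frames)
print(f"MOTA {ev.mota:.3f}  IDF1 {ev.idf1:.3f}  IDS {ev.ids}  "
      f"FP {ev.fp}  FN {ev.fn}")
```

Output:

```
MOTA 0.886  IDF1 0.940  IDS 0  FP 0  FN 114
```

All 20 synthetic cells are tracked without a single identity switch; the
114 false negatives are exactly the detections the occlusion model
removed (the tracker bridges those gaps rather than fragmenting tracks),
and MOTA = 1 − (FN+FP+IDS)/1000 ≈ 0.886.

Short narrative scripts for each capability live in `examples/`
(simulation, DPE segmentation of a star-shaped cell, tracking under
occlusion, morphometry and motility cohorts).

## Command line

```bash
dpetrack simulate --config scene.yaml --out-dir sim/
dpetrack segment  --images sim/stack.tif --out instances.json
dpetrack track    --instances instances.json --out tracks.csv
dpetrack evaluate --pred tracks.csv --gt sim/gt_tracks.csv --out report.json
dpetrack analyze  --tracks tracks.csv --instances instances.json \
                  --pixel-size 0.8 --out analysis/
dpetrack train-segmenter --data-dir sim/ --out weights.npz
dpetrack train-tracker   --data-dir sim/ --out tweights.npz
```

Formats: polygons as JSON (`{frame, id, score, vertices}`), tracks and
morphometry as CSV with a `# key: value` metadata header, stacks as
multipage TIFF or PNG directories, configuration as strict YAML.

## Documentation

`docs/methods.md` describes the models, parameter defaults, the
synthetic-data assumptions and their limits, and the numerical choices
(tolerances, tie-breaks, repair strategies) in detail.
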