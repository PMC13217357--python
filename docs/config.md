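# Configuration reference

`dpetrack` reads a single YAML file with one section per pipeline stage.
Unknown top-level keys are rejected (typos fail loudly). All keys are
optional; a bare (empty) config runs end to end with the defaults below.
Frame indices are 0-based everywhere.

```yaml
seed: 0              # global seed; fans out per module via fixed offsets
log_level: info
pixel_size: 1.0      # micrometres per pixel (applied only at analysis)
frame_interval: 10.0 # minutes between frames

simulate:            # SceneConfig fields
  width: 256
  height: 256
  n_cells: 20
  radius_mean: 10.0          # px
  radius_sd: 1.5
  eccentricity_range: [0.55, 0.9]   # ellipse minor/major
  n_protrusions: [2, 5]             # inclusive range per cell
  protrusion_length: [4.0, 10.0]    # px
  protrusion_width: 0.22            # radians
  step_shape: 2.0                   # gamma shape of per-frame step
  step_scale: 1.25                  # gamma scale (px)
  persistence: 0.6                  # heading turn sd (radians)
  motility: 1.0                     # step multiplier ("stress" < 1)
  drop_prob: 0.0                    # detection drop probability
  max_consecutive_drops: 2
  overlap_event_rate: 0.0           # fraction of cells steered to overlap
  noise_sd: 0.02
  background: 0.75
  cell_intensity: 0.35
  frame_interval: 10.0              # minutes
  duration: 1200.0                  # minutes (1200/10 -> 121 frames)
  seed: 0

backbone:
  channels: [16, 32, 64]   # widths at strides 4 / 8 / 16
  order: 3                 # Fourier harmonics G
  # input_scale defaults to pi

segmenter:
  n_vertices: 128          # contour vertices N
  r_max: 4.0               # offset bound (px), tanh-scaled
  score_thr: 0.3           # detection heat threshold
  nms_iou: 0.5
  mlp_passes: 1
  dpe_max_iter: 50
  dpe_tol: 0.05            # px mean displacement
  min_area: 30.0           # px^2
  smooth_window: 5

tracker:
  s_tau: 0.5               # match threshold on S_sim
  top_k: 200               # per frame
  max_gap: 3               # occlusion frames before termination
  rounds: 3                # message-passing rounds T
  gate_radius: null        # px; null -> 3x mean cell diameter
  mhd_matrix: inverse_cov  # or literal_sigma

quantify:
  # reserved; pixel_size and frame_interval above cover the analysis stage
```

Every output file records the tool version and a hash of the resolved
configuration (JSON `meta` block, or `# key: value` CSV header lines).
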