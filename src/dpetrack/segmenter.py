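"""Instance segmentation by dynamic contour evolution.

Pipeline per frame:

1. the backbone produces a feature pyramid and a centre heatmap / box-size
   head proposes detections (peak decoding + NMS);
2. an ellipse inscribed in each detected box provides the initial contour;
3. the Boundary Feature Enhancement (BFE) head predicts per-vertex offsets
   from sampled features concatenated with the local Freeman chain-code
   direction of the discretised contour;
4. an MLP head, a circular 1-D convolution over the whole vertex-feature
   sequence, refines the contour for a configurable number of passes;
5. Dynamic Profile Evolution (DPE) extracts cellular landmarks (skeleton
   endpoints extended to the boundary plus boundary-saliency maxima) and
   iteratively stretches or contracts vertices along their outward normals
   toward the landmarks and the image boundary evidence until convergence;
6. postprocessing smooths contours, drops sub-area noise and deduplicates.

A reduced-scale trainer fits the detection and offset heads on synthetic
sequences with the exponential learning-rate decay schedule
``L_{i+1} = L_i * gamma`` applied every ``decay_every`` epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.morphology import skeletonize

from . import geometry, nn
from .backbone import Backbone, Conv2d, FeaturePyramid
from .geometry import Contour
from .nn import Linear, Module, Parameter, Tensor, bilinear_sample

__all__ = [
    "CellInstance",
    "Landmarks",
    "TrainingSchedule",
    "SegmenterNet",
    "Segmenter",
    "detect",
    "decode_detections",
    "init_contour",
    "bfe_offsets",
    "mlp_offsets",
    "extract_landmarks",
    "dpe_evolve",
    "postprocess",
    "lr_at_epoch",
    "train_segmenter",
    "boxes_iou",
]


@dataclass
class CellInstance:
    """One detected cell in one frame."""

    frame: int
    contour: Contour
    score: float
    id: int | None = None
    appearance: np.ndarray | None = None
    bbox: tuple[float, float, float, float] | None = None  # x, y, w, h

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")
        if self.bbox is None:
            v = self.contour.vertices
            x0, y0 = v.min(axis=0)
            x1, y1 = v.max(axis=0)
            self.bbox = (float(x0), float(y0), float(x1 - x0), float(y1 - y0))
        if self.appearance is not None:
            self.appearance = np.asarray(self.appearance, dtype=float)
            if not np.all(np.isfinite(self.appearance)):
                raise ValueError("appearance vector must be finite")

    @property
    def centroid(self) -> np.ndarray:
        return geometry.polygon_centroid(self.contour)

    @property
    def area(self) -> float:
        return geometry.polygon_area(self.contour)


@dataclass
class Landmarks:
    """Salient key points (protrusion tips, boundary ridges) of one cell."""

    points: np.ndarray          # (M, 2) x, y
    weights: np.ndarray         # (M,) saliency >= 0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if len(self.points) < 1:
            raise ValueError("at least one landmark required")
        if np.any(self.weights < 0):
            raise ValueError("landmark weights must be non-negative")


@dataclass
class TrainingSchedule:
    """Exponential step-decay learning-rate schedule and run sizes."""

    L0: float = 1e-5
    gamma: float = 0.1
    decay_every: int = 50
    epochs: int = 200
    batch_size: int = 4
    dropout_p: float = 0.1

    def __post_init__(self) -> None:
        if self.L0 < 0:
            raise ValueError("initial learning rate must be non-negative")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")


def lr_at_epoch(schedule: TrainingSchedule, epoch: int) -> float:
    """L0 * gamma ** floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return schedule.L0 * schedule.gamma ** (epoch // schedule.decay_every)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def boxes_iou(a, b) -> float:
    """IoU of two (x, y, w, h) axis-aligned boxes."""
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix = max(0.0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def decode_detections(heatmap: np.ndarray, sizemap: np.ndarray, stride: int,
                      score_thr: float = 0.3, nms_iou: float = 0.5,
                      min_distance: int = 2) -> list[tuple]:
    """Peak decoding of a centre heatmap into (bbox, center, score) triples.

    ``sizemap`` holds log box width/height (in image pixels) per cell.
    """
    peaks = peak_local_max(heatmap, min_distance=min_distance,
                           threshold_abs=score_thr, exclude_border=False)
    dets = []
    for r, c in peaks:
        score = float(heatmap[r, c])
        w = float(np.exp(np.clip(sizemap[0, r, c], -4, 6)))
        h = float(np.exp(np.clip(sizemap[1, r, c], -4, 6)))
        cx, cy = (c + 0.5) * stride, (r + 0.5) * stride
        dets.append(((cx - w / 2, cy - h / 2, w, h), (cx, cy), score))
    dets.sort(key=lambda d: -d[2])
    kept: list[tuple] = []
    for d in dets:
        if all(boxes_iou(d[0], k[0]) <= nms_iou for k in kept):
            kept.append(d)
    return kept


class SegmenterNet(Module):
    """Backbone plus detection and contour-offset heads."""

    def __init__(self, channels=(16, 32, 64), order: int = 3,
                 n_vertices: int = 128, r_max: float = 4.0,
                 hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_vertices = n_vertices
        self.r_max = r_max
        self.backbone = Backbone(channels=channels, order=order, seed=seed)
        c1 = channels[0]
        # detection heads see the backbone features plus a pooled-intensity
        # skip channel (cells are intensity blobs; the shortcut lets the
        # centre heat learn quickly at desk scale)
        self.heat_head = Conv2d(c1 + 1, 1, k=3, rng=rng)
        # start the centre heat at a low prior (p ~ 0.1) so training begins
        # near the background optimum instead of collapsing toward it
        self.heat_head.b.data[:] = -2.197
        self.size_head = Conv2d(c1 + 1, 2, k=3, rng=rng)
        # BFE: per-vertex [sampled feature | chain-code one-hot] -> offset
        self.bfe_h = Linear(c1 + 8, hidden, rng=rng)
        self.bfe_o = Linear(hidden, 2, rng=rng, zero_init=True)
        # MLP stage: circular conv over the vertex-feature sequence
        self.mlp_c = Linear(3 * (c1 + 2), hidden, rng=rng)
        self.mlp_o = Linear(hidden, 2, rng=rng, zero_init=True)

    # -- persistence --------------------------------------------------------
    def save(self, path: str) -> None:
        np.savez(path, **self.named_arrays())

    @classmethod
    def load(cls, path: str, **kwargs) -> "SegmenterNet":
        arrs = dict(np.load(path))
        c1 = arrs["heat_head.W"].shape[0] // 9 - 1
        net = cls(channels=(c1, 2 * c1, 4 * c1), **kwargs)
        net.load_arrays(arrs)
        return net

    # -- heads ----------------------------------------------------------------
    @staticmethod
    def det_input(p4: Tensor, images: np.ndarray) -> Tensor:
        """Concatenate stride-4 features with 4x4 average-pooled intensity."""
        B, H, W = images.shape
        h4, w4 = p4.data.shape[2], p4.data.shape[3]
        pooled = images[:, :h4 * 4, :w4 * 4].reshape(B, h4, 4, w4, 4).mean((2, 4))
        return nn.concat([p4, Tensor(pooled[:, None])], axis=1)

    def heatmap_tensor(self, det_in: Tensor) -> Tensor:
        return self.heat_head(det_in).sigmoid()

    def sizemap_tensor(self, det_in: Tensor) -> Tensor:
        return self.size_head(det_in)


def detect(pyramid: FeaturePyramid, net: SegmenterNet,
           score_thr: float = 0.3, nms_iou: float = 0.5) -> list[tuple]:
    """Decode detections from the stride-4 pyramid level."""
    p4 = Tensor(np.asarray(pyramid.level(4))[None])
    det_in = net.det_input(p4, np.asarray(pyramid.image)[None])
    heat = net.heatmap_tensor(det_in).data[0, 0]
    size = net.sizemap_tensor(det_in).data[0]
    return decode_detections(heat, size, stride=4,
                             score_thr=score_thr, nms_iou=nms_iou)


# ---------------------------------------------------------------------------
# Initial contour and learned offsets
# ---------------------------------------------------------------------------

def init_contour(bbox, n_vertices: int = 128) -> Contour:
    """Ellipse inscribed in the box, n vertices equally spaced in angle, CCW."""
    if n_vertices < 8:
        raise ValueError("initial contour needs at least 8 vertices")
    x, y, w, h = bbox
    if w <= 0 or h <= 0:
        raise ValueError("degenerate bounding box")
    cx, cy = x + w / 2.0, y + h / 2.0
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    vx = cx + (w / 2.0) * np.cos(theta)
    vy = cy + (h / 2.0) * np.sin(theta)
    return Contour.from_vertices(np.column_stack([vx, vy]))


def chain_direction_onehot(contour: Contour) -> np.ndarray:
    """One-hot Freeman direction of each vertex's step to its successor.

    The polygon edge direction is quantised into the 8 Freeman sectors
    (code 0 = east, advancing counter-clockwise on screen, i.e. code 2
    points up / -y), mirroring the discretised boundary chain code.
    """
    v = contour.vertices
    d = np.roll(v, -1, axis=0) - v
    ang = np.arctan2(-d[:, 1], d[:, 0])      # screen y points down
    code = np.round(ang / (np.pi / 4.0)).astype(int) % 8
    onehot = np.zeros((len(v), 8))
    onehot[np.arange(len(v)), code] = 1.0
    return onehot


def _offset_from_head(raw: Tensor, r_max: float) -> Tensor:
    return raw.tanh() * r_max


def bfe_offsets(contour: Contour, pyramid: FeaturePyramid, net: SegmenterNet,
                train: bool = False, dropout_rng=None, dropout_p: float = 0.0):
    """Boundary-feature-enhancement offsets: contour + per-vertex prediction.

    Each vertex contributes its bilinearly sampled stride-4 feature vector
    concatenated with the one-hot chain-code direction; a two-layer head
    maps this to a 2D offset bounded by tanh * r_max.
    """
    fmap = pyramid.level(4)
    f = fmap if isinstance(fmap, Tensor) else Tensor(np.asarray(fmap))
    pts = Tensor(contour.vertices)
    feats = bilinear_sample(f, pts, stride=4.0)
    onehot = Tensor(chain_direction_onehot(contour))
    h = nn.concat([feats, onehot], axis=1)
    h = net.bfe_h(h).relu()
    if train and dropout_p > 0:
        mask = (dropout_rng.random(h.shape) >= dropout_p) / (1 - dropout_p)
        h = h * Tensor(mask)
    off = _offset_from_head(net.bfe_o(h), net.r_max)
    if train:
        return off
    return Contour(contour.vertices + off.data)


def mlp_offsets(contour: Contour, pyramid: FeaturePyramid, net: SegmenterNet,
                passes: int = 1, train: bool = False,
                dropout_rng=None, dropout_p: float = 0.0):
    """Sequence-conditioned refinement: circular 1-D conv + MLP over vertices.

    Each pass samples features at the current vertices, concatenates each
    vertex's feature window (previous, self, next) with its normalised
    position, and predicts bounded offsets.  With zero head weights the
    operation is the identity.
    """
    fmap = pyramid.level(4)
    f = fmap if isinstance(fmap, Tensor) else Tensor(np.asarray(fmap))
    H = f.data.shape[-2] * 4.0
    W = f.data.shape[-1] * 4.0
    verts = contour.vertices.copy()
    total_off = None
    for _ in range(max(passes, 0)):
        pts = Tensor(verts, requires_grad=train)
        feats = bilinear_sample(f, pts, stride=4.0)
        rel = Tensor(np.column_stack([verts[:, 0] / W, verts[:, 1] / H]))
        x = nn.concat([feats, rel], axis=1)                 # (N, c1+2)
        window = nn.concat([x[_rolled(len(verts), -1)],
                            x,
                            x[_rolled(len(verts), +1)]], axis=1)
        h = net.mlp_c(window).relu()
        if train and dropout_p > 0:
            mask = (dropout_rng.random(h.shape) >= dropout_p) / (1 - dropout_p)
            h = h * Tensor(mask)
        off = _offset_from_head(net.mlp_o(h), net.r_max)
        verts = verts + off.data
        total_off = off if total_off is None else total_off + off
    if train:
        return total_off if total_off is not None else Tensor(np.zeros_like(verts))
    return Contour(verts)


def _rolled(n: int, shift: int) -> np.ndarray:
    return np.roll(np.arange(n), shift)


# ---------------------------------------------------------------------------
# Landmarks and Dynamic Profile Evolution
# ---------------------------------------------------------------------------

def _sample_image(image: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(image, [pts[:, 1], pts[:, 0]],
                                   order=1, mode="nearest")


def extract_landmarks(image: np.ndarray, contour_or_instance,
                      n_saliency: int = 8) -> Landmarks:
    """Key cellular landmarks: protrusion tips and boundary-saliency maxima.

    Tips come from skeleton endpoints of the instance mask, each extended
    radially (away from the centroid) to the last mask pixel so that the
    landmark sits on the protrusion tip rather than inside the taper.
    Boundary saliency adds local maxima of the gradient magnitude sampled
    along the current contour.  A flat patch falls back to the contour
    vertices so at least one landmark is always returned.
    """
    contour = getattr(contour_or_instance, "contour", contour_or_instance)
    image = np.asarray(image, dtype=float)
    mask = geometry.rasterize_contour(contour, image.shape)
    grad = ndimage.gaussian_gradient_magnitude(image, sigma=1.0)
    centroid = geometry.polygon_centroid(contour)

    points: list[np.ndarray] = []
    weights: list[float] = []

    if mask.any():
        skel = skeletonize(mask)
        nb = ndimage.convolve(skel.astype(int), np.ones((3, 3)), mode="constant")
        ends = np.argwhere(skel & (nb == 2))        # pixel itself + 1 neighbour
        for r, c in ends:
            p = np.array([c, r], dtype=float)
            d = p - centroid
            norm = np.linalg.norm(d)
            if norm < 1e-6:
                continue
            d /= norm
            tip = p.copy()
            q = p.copy()
            for _ in range(2 * max(image.shape)):
                q = q + 0.5 * d
                iy, ix = int(round(q[1])), int(round(q[0]))
                if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]) \
                        or not mask[iy, ix]:
                    break
                tip = q.copy()
            points.append(tip)
            weights.append(float(grad[int(round(tip[1])), int(round(tip[0]))]) + 1e-6)

    # boundary saliency maxima along the contour
    dense = geometry.resample_contour(contour, max(64, len(contour))).vertices
    sal = _sample_image(grad, dense)
    if sal.max() > 1e-9:
        is_max = (sal >= np.roll(sal, 1)) & (sal >= np.roll(sal, -1))
        idx = np.argwhere(is_max).ravel()
        idx = idx[np.argsort(sal[idx])[::-1][:n_saliency]]
        for i in idx:
            points.append(dense[i])
            weights.append(float(sal[i]) + 1e-6)

    if not points:
        pts = contour.vertices
        return Landmarks(points=pts, weights=np.ones(len(pts)))
    return Landmarks(points=np.asarray(points), weights=np.asarray(weights))


def _outward_normals(verts: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    tang = np.roll(verts, -1, axis=0) - np.roll(verts, 1, axis=0)
    n = np.column_stack([tang[:, 1], -tang[:, 0]])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    n = n / norms
    # orient away from the centroid (cells are star-shaped to good approx.)
    flip = np.einsum("ij,ij->i", n, verts - centroid) < 0
    n[flip] *= -1.0
    return n


def _repair_simple(verts: np.ndarray) -> np.ndarray:
    """Repair self-intersections by progressively reprojecting the contour
    onto smoothed versions of itself."""
    if geometry.is_simple(verts):
        return verts
    for window in (3, 5, 7, 9, 13):
        sm = geometry.smooth_contour(Contour.from_vertices(verts), window).vertices
        if geometry.is_simple(sm):
            return sm
    hull_idx = _convex_hull_indices(verts)
    return verts[hull_idx]


def _convex_hull_indices(verts: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    return ConvexHull(verts).vertices


def dpe_evolve(contour: Contour, landmarks: Landmarks, pyramid,
               max_iter: int = 50, tol: float = 0.05,
               alpha: float = 1.0, capture_radius: float = 6.0,
               net: SegmenterNet | None = None,
               log: list | None = None) -> tuple[Contour, int]:
    """Iterative Dynamic Profile Evolution of one contour.

    Per iteration every vertex moves along its outward normal by an
    adaptive step combining (a) region evidence — outward while the vertex
    still samples cell-interior intensity, inward over background — and
    (b) attraction toward the nearest landmark within the capture radius,
    weighted by its saliency.  Per-vertex steps halve whenever their region
    force flips sign (bisection onto the boundary) and anneal globally, so
    the mean displacement decreases; the loop stops when it falls below
    ``tol`` or after ``max_iter`` iterations.  Self-intersections are
    repaired by reprojection onto a smoothed contour.  When ``net`` is
    given, its MLP head adds a learned residual offset each iteration.

    Parameters are in pixels; ``pyramid`` may be a FeaturePyramid (its
    source image is used) or a raw 2D image.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    image = pyramid.image if isinstance(pyramid, FeaturePyramid) else np.asarray(pyramid, float)

    n = len(contour)
    verts = geometry.resample_contour(contour, n).vertices
    mask0 = geometry.rasterize_contour(verts, image.shape)
    if mask0.any():
        mean_in = float(image[mask0].mean())
        mean_out = float(image[~mask0].mean()) if (~mask0).any() else mean_in + 1e-3
    else:
        mean_in, mean_out = float(image.min()), float(image.max())
    thr = 0.5 * (mean_in + mean_out)
    polarity = 1.0 if mean_out > mean_in else -1.0   # +1: cells darker than bg

    lm_pts, lm_w = landmarks.points, landmarks.weights
    w_norm = lm_w / (lm_w.max() + 1e-12)

    steps = np.full(n, alpha)
    prev_sign = np.zeros(n)
    prev_disp = np.inf
    iters_used = 0
    for it in range(max_iter):
        iters_used = it + 1
        if it > 0 and it % 8 == 0:
            # redistribute vertices so concavities stay covered
            verts = geometry.resample_contour(Contour.from_vertices(verts), n).vertices
            prev_sign = np.zeros(n)
            steps = np.full(n, alpha * 0.985 ** it)
        centroid = verts.mean(axis=0)
        normals = _outward_normals(verts, centroid)
        intensity = _sample_image(image, verts)
        # region force: fraction of the interior/background contrast
        f = np.clip(polarity * (thr - intensity) / (abs(mean_out - mean_in) / 2 + 1e-9),
                    -1.0, 1.0)
        sign = np.sign(f)
        flipped = (sign != prev_sign) & (prev_sign != 0)
        steps[flipped] *= 0.5
        prev_sign = sign
        move = normals * (steps * f)[:, None]

        # landmark attraction within the capture radius
        nd = None
        if len(lm_pts):
            diff = lm_pts[None, :, :] - verts[:, None, :]
            dist = np.hypot(diff[..., 0], diff[..., 1])
            nearest = dist.argmin(axis=1)
            nd = dist[np.arange(n), nearest]
            in_range = nd < capture_radius
            if in_range.any():
                pull = diff[np.arange(n), nearest]
                scale = np.minimum(nd, steps) / (nd + 1e-9)
                wgt = w_norm[nearest]
                move[in_range] = (pull * (scale * wgt)[:, None])[in_range]

        if net is not None and isinstance(pyramid, FeaturePyramid):
            res = mlp_offsets(Contour.from_vertices(verts), pyramid, net, passes=1)
            move = move + 0.25 * (res.vertices - verts)

        new_verts = verts + move
        # curvature regularisation, active only near the boundary (weak
        # region force) and away from landmark-captured vertices
        sm = geometry.smooth_contour(Contour.from_vertices(new_verts), 3).vertices
        blend = 0.15 * (1.0 - np.abs(f))
        if nd is not None:
            blend[nd < capture_radius] = 0.0
        new_verts = new_verts * (1 - blend[:, None]) + sm * blend[:, None]

        delta = new_verts - verts
        disp = float(np.mean(np.hypot(delta[:, 0], delta[:, 1])))
        # monotone trust region: never move further (on average) than the
        # previous iteration, so the displacement log is non-increasing
        if disp > prev_disp and disp > 0:
            new_verts = verts + delta * (prev_disp / disp)
            disp = prev_disp
        prev_disp = disp
        if log is not None:
            log.append(disp)
        verts = new_verts
        steps *= 0.985
        if disp < tol:
            break

    verts = _repair_simple(verts)
    out = geometry.resample_contour(Contour.from_vertices(verts), n)
    return out, iters_used


# ---------------------------------------------------------------------------
# Postprocessing
# ---------------------------------------------------------------------------

def postprocess(instances: list[CellInstance], min_area: float = 30.0,
                smooth_window: int = 5, dedup_iou: float = 0.8) -> list[CellInstance]:
    """Smooth contours, drop sub-area noise, deduplicate overlapping instances."""
    smoothed = []
    for inst in instances:
        c = geometry.smooth_contour(inst.contour, smooth_window)
        smoothed.append(CellInstance(frame=inst.frame, contour=c, score=inst.score,
                                     id=inst.id, appearance=inst.appearance))
    kept = geometry.remove_noise(smoothed, min_area)
    kept.sort(key=lambda i: -i.score)
    final: list[CellInstance] = []
    for inst in kept:
        if all(geometry.polygon_iou(inst.contour, k.contour) < dedup_iou
               for k in final):
            final.append(inst)
    return final


# ---------------------------------------------------------------------------
# Full-frame segmentation
# ---------------------------------------------------------------------------

class Segmenter:
    """End-to-end per-frame segmentation with the trained (or fresh) net."""

    def __init__(self, net: SegmenterNet | None = None, score_thr: float = 0.3,
                 nms_iou: float = 0.5, mlp_passes: int = 1,
                 dpe_max_iter: int = 50, dpe_tol: float = 0.05,
                 min_area: float = 30.0, smooth_window: int = 5,
                 use_learned_offsets: bool = True):
        self.net = net or SegmenterNet()
        self.score_thr = score_thr
        self.nms_iou = nms_iou
        self.mlp_passes = mlp_passes
        self.dpe_max_iter = dpe_max_iter
        self.dpe_tol = dpe_tol
        self.min_area = min_area
        self.smooth_window = smooth_window
        self.use_learned_offsets = use_learned_offsets

    def segment_frame(self, image: np.ndarray, frame: int = 0) -> list[CellInstance]:
        image = np.asarray(image, dtype=float)
        pyramid = self.net.backbone(image)
        dets = detect(pyramid, self.net, self.score_thr, self.nms_iou)
        instances: list[CellInstance] = []
        for bbox, _center, score in dets:
            contour = init_contour(bbox, self.net.n_vertices)
            if self.use_learned_offsets:
                contour = bfe_offsets(contour, pyramid, self.net)
                contour = mlp_offsets(contour, pyramid, self.net,
                                      passes=self.mlp_passes)
            lms = extract_landmarks(image, contour)
            contour, _ = dpe_evolve(contour, lms, pyramid,
                                    max_iter=self.dpe_max_iter, tol=self.dpe_tol)
            app = appearance_vector(pyramid, contour)
            instances.append(CellInstance(frame=frame, contour=contour,
                                          score=min(max(score, 0.0), 1.0),
                                          appearance=app))
        return postprocess(instances, self.min_area, self.smooth_window)

    def segment_stack(self, frames) -> list[list[CellInstance]]:
        return [self.segment_frame(f, i) for i, f in enumerate(frames)]


def appearance_vector(pyramid: FeaturePyramid, contour: Contour) -> np.ndarray:
    """Mean stride-4 backbone feature over the contour vertices (node feature v)."""
    fmap = pyramid.level(4)
    f = fmap if isinstance(fmap, Tensor) else Tensor(np.asarray(fmap))
    pts = Tensor(geometry.resample_contour(contour, 32).vertices)
    feats = bilinear_sample(f, pts, stride=4.0)
    return feats.data.mean(axis=0)


# ---------------------------------------------------------------------------
# Training (reduced scale)
# ---------------------------------------------------------------------------

def _gt_heatmap(shape, centers, sizes, stride: int = 4) -> np.ndarray:
    """Penalty-reduced Gaussian target heatmap on the stride-4 grid."""
    H, W = shape
    hm = np.zeros((H, W))
    yy, xx = np.mgrid[0:H, 0:W]
    for (cx, cy), (w, h) in zip(centers, sizes):
        sigma = max(min(w, h) / stride / 3.0, 1.0)
        gx, gy = cx / stride - 0.5, cy / stride - 0.5
        g = np.exp(-((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * sigma ** 2))
        hm = np.maximum(hm, g)
    return hm


def _focal_loss(pred: Tensor, gt: np.ndarray) -> Tensor:
    """CenterNet-style penalty-reduced focal loss."""
    eps = 1e-6
    pos = (gt > 0.999).astype(float)
    n_pos = max(pos.sum(), 1.0)
    p = pred * (1 - 2 * eps) + eps
    pos_t = Tensor(pos)
    neg_w = Tensor((1 - gt) ** 4 * (1 - pos))
    loss_pos = (p.log() * ((1 - p) * (1 - p)) * pos_t).sum()
    loss_neg = ((1 - p).log() * (p * p) * neg_w).sum()
    return -(loss_pos + loss_neg) * (1.0 / n_pos)


def _smooth_l1(diff: Tensor) -> Tensor:
    # Charbonnier smooth-L1 surrogate (smooth everywhere, same tails)
    return ((diff * diff + 1e-4) ** 0.5).mean()


def _align_gt_polygon(gt: Contour, ellipse: Contour) -> np.ndarray:
    """Resample GT to the ellipse's vertex count and cyclically align it by
    the angle of the first ellipse vertex from the GT centroid."""
    n = len(ellipse)
    gt_rs = geometry.resample_contour(gt, n).vertices
    centroid = geometry.polygon_centroid(gt)
    ang_gt = np.arctan2(gt_rs[:, 1] - centroid[1], gt_rs[:, 0] - centroid[0])
    e0 = ellipse.vertices[0]
    ang0 = math.atan2(e0[1] - centroid[1], e0[0] - centroid[0])
    shift = int(np.argmin(np.abs(np.angle(np.exp(1j * (ang_gt - ang0))))))
    return np.roll(gt_rs, -shift, axis=0)


def train_segmenter(dataset, schedule: TrainingSchedule, seed: int = 0,
                    net: SegmenterNet | None = None,
                    vertex_loss_weight: float = 0.05,
                    size_loss_weight: float = 0.1,
                    progress: bool = False):
    """Fit detection and offset heads on (image, gt_contours) pairs.

    ``dataset`` is a sequence of ``(image, [Contour, ...])`` tuples.  Loss =
    centre focal loss + L1 on log box sizes + smooth-L1 on vertex offsets
    against arc-length-aligned ground-truth polygons (GT matched to
    detections by Hungarian assignment on centre distance; during training
    the GT boxes themselves seed the contour heads).  Returns the net and a
    per-epoch loss log.  Deterministic for a fixed seed (single-threaded).
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)
    net = net or SegmenterNet(seed=seed)
    params = net.parameters()
    opt = nn.Adam(params, lr=lr_at_epoch(schedule, 0))
    log: list[float] = []

    prepared = []
    for image, gts in dataset:
        image = np.asarray(image, dtype=float)
        centers = [geometry.polygon_centroid(g) for g in gts]
        boxes = []
        for g in gts:
            v = g.vertices
            x0, y0 = v.min(axis=0)
            x1, y1 = v.max(axis=0)
            boxes.append((float(x0), float(y0), float(x1 - x0), float(y1 - y0)))
        h4, w4 = image.shape[0] // 4, image.shape[1] // 4
        hm = _gt_heatmap((h4, w4), centers, [(b[2], b[3]) for b in boxes])
        prepared.append((image, gts, centers, boxes, hm))

    n_batches = max(len(prepared) // schedule.batch_size, 1)
    for epoch in range(schedule.epochs):
        opt.lr = lr_at_epoch(schedule, epoch)
        order = rng.permutation(len(prepared))
        epoch_loss = 0.0
        for b in range(n_batches):
            idx = order[b * schedule.batch_size:(b + 1) * schedule.batch_size]
            if len(idx) == 0:
                continue
            opt.zero_grad()
            batch_imgs = np.stack([prepared[i][0] for i in idx])
            x = Tensor(batch_imgs[:, None])
            p4, _, _ = net.backbone.forward_tensor(x)
            det_in = net.det_input(p4, batch_imgs)
            heat = net.heatmap_tensor(det_in)
            size = net.sizemap_tensor(det_in)
            loss = Tensor(0.0)
            for bi, i in enumerate(idx):
                image, gts, centers, boxes, hm = prepared[i]
                loss = loss + _focal_loss(heat[bi, 0], hm)
                if boxes:
                    rows = np.clip((np.array(centers)[:, 1] / 4 - 0.5).round().astype(int),
                                   0, hm.shape[0] - 1)
                    cols = np.clip((np.array(centers)[:, 0] / 4 - 0.5).round().astype(int),
                                   0, hm.shape[1] - 1)
                    tgt = np.log(np.maximum(np.array(boxes)[:, 2:4], 1e-3))
                    pred_sz = size[bi].transpose(1, 2, 0)[rows, cols]
                    loss = loss + _smooth_l1(pred_sz - Tensor(tgt)) * size_loss_weight
                # contour heads, seeded from GT boxes (teacher forcing)
                pyr_t = FeaturePyramid(levels=[(4, p4.data.shape[1], p4[bi])],
                                       image=image)
                for g, box in zip(gts, boxes):
                    ellipse = init_contour(box, net.n_vertices)
                    target = _align_gt_polygon(g, ellipse)
                    off1 = bfe_offsets(ellipse, pyr_t, net, train=True,
                                       dropout_rng=rng, dropout_p=schedule.dropout_p)
                    c1 = Contour(ellipse.vertices + off1.data)
                    off2 = mlp_offsets(c1, pyr_t, net, passes=1, train=True,
                                       dropout_rng=rng, dropout_p=schedule.dropout_p)
                    pred = Tensor(ellipse.vertices) + off1 + off2
                    loss = loss + _smooth_l1(pred - Tensor(target)) * vertex_loss_weight
            loss = loss * (1.0 / len(idx))
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
        log.append(epoch_loss / n_batches)
        if progress:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  loss {log[-1]:.4f}")
    return net, log
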