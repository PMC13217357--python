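"""Multi-Feature Similarity-Boosted graph tracking.

Consecutive frames form a bipartite graph: left nodes are the previous
frame's cells (features ``v_i^{t-1}``), right nodes the current frame's
(``v_j^t``).  Edge features are initialised from three pairwise
similarities,

    e0_ij = f(IoU_ij, Sim_ij, Contour_ij),

where ``f`` is a fully connected layer, IoU is the polygon overlap, Sim
the cosine similarity of the node feature vectors and Contour the bounded
contour-shape similarity; the directions ``e_ij`` and ``e_ji`` are
distinct features carrying separate direction encodings.  Message passing
then boosts likely matches using the Mahalanobis distance between node
features and the summed shape similarity,

    e_ij^t = f_e(e0_ij, e_ij^{t-1}, v_i^{t-1}, v_j^t, MhD_ij, shape_ij),

with nodes aggregating incident edge features through a learned map
followed by a sum.  An edge-confidence head squashes the final features to
a matching probability S_sim (mean of the two direction scores); pairs are
matched one-to-one by optimal assignment over edges with S_sim above the
threshold S_tau.  Unmatched previous-frame cells enter an occluded state
for up to ``max_gap`` frames, re-entering later graphs with their
last-seen features, which preserves identities across detection drops.

Edges are stored as flat arrays so the message-passing rounds are a few
matrix products regardless of graph size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import geometry, nn
from .nn import Linear, Module, Parameter, Tensor
from .segmenter import CellInstance

__all__ = [
    "FrameGraph",
    "MatchResult",
    "Track",
    "TrackerNet",
    "TrackerParams",
    "select_topk",
    "cosine_sim",
    "mahalanobis",
    "pair_features",
    "init_edge",
    "build_graph",
    "update_graph",
    "edge_confidence",
    "all_confidences",
    "match",
    "link_tracks",
    "train_tracker",
    "edge_accuracy",
]


def select_topk(instances: list[CellInstance], k: int) -> list[CellInstance]:
    """K highest-score instances; ties broken by larger area, then lower index."""
    if k < 1:
        raise ValueError("K must be >= 1")
    keyed = [(-inst.score, -inst.area, idx, inst)
             for idx, inst in enumerate(instances)]
    keyed.sort(key=lambda t: t[:3])
    return [t[3] for t in keyed[:k]]


def cosine_sim(v_a, v_b) -> float:
    """dot(a, b) / (|a||b|); zero vectors score 0 with a warning."""
    a, b = np.asarray(v_a, float), np.asarray(v_b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("cosine similarity of a zero vector defined as 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def mahalanobis(v_a, v_b, M) -> float:
    """((a - b)^T M (a - b))^{1/2} for symmetric positive-semidefinite M."""
    d = np.asarray(v_a, float) - np.asarray(v_b, float)
    M = np.asarray(M, float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("M must be symmetric")
    q = float(d @ M @ d)
    if q < -1e-9:
        raise ValueError("M must be positive-semidefinite")
    return float(np.sqrt(max(q, 0.0)))


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]
    births: list[int]       # unmatched right nodes
    deaths: list[int]       # unmatched left nodes (occlusion candidates)


@dataclass
class Track:
    track_id: int
    observations: list[tuple[int, CellInstance]] = field(default_factory=list)
    state: str = "active"                  # active | occluded | terminated
    gap: int = 0

    def last(self) -> tuple[int, CellInstance]:
        return self.observations[-1]


class TrackerNet(Module):
    """Learnable maps of the similarity-boosted GNN."""

    def __init__(self, d_v: int = 8, d_e: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d_v, self.d_e = d_v, d_e
        self.f_init = Linear(3, d_e, rng=rng)
        self.dir_fwd = Parameter(np.zeros(d_e))
        self.dir_bwd = Parameter(np.zeros(d_e))
        self.f_e = Linear(2 * d_e + 2 * d_v + 2, d_e, rng=rng)
        self.v_self = Linear(d_v, d_v, rng=rng)
        self.v_agg = Linear(d_e, d_v, rng=rng)
        self.clas = Linear(d_e, 1, rng=rng)

    @classmethod
    def default(cls, d_v: int = 8) -> "TrackerNet":
        """Hand-set weights giving a sensible untrained score:
        S_sim ~ sigmoid(4*IoU + 2*cos + 2*contour - 4)."""
        net = cls(d_v=d_v, d_e=3, seed=0)
        net.f_init.W.data = np.eye(3)
        net.f_init.b.data = np.zeros(3)
        net.f_e.W.data = np.zeros_like(net.f_e.W.data)
        net.f_e.W.data[:3, :3] = np.eye(3) * 2.0     # tanh(2x): soft pass-through of e0
        net.f_e.b.data = np.zeros(3)
        net.v_self.W.data = np.eye(d_v)
        net.v_self.b.data = np.zeros(d_v)
        net.v_agg.W.data = np.zeros_like(net.v_agg.W.data)
        net.clas.W.data = np.array([[4.0], [2.0], [2.0]])
        net.clas.b.data = np.array([-4.0])
        return net

    def save(self, path: str) -> None:
        np.savez(path, **self.named_arrays())

    @classmethod
    def load(cls, path: str) -> "TrackerNet":
        arrs = dict(np.load(path))
        d_e = arrs["f_init.W"].shape[1]
        d_v = arrs["v_self.W"].shape[0]
        net = cls(d_v=d_v, d_e=d_e)
        net.load_arrays(arrs)
        return net


@dataclass
class FrameGraph:
    """Bipartite graph between frames t-1 and t, edges as flat arrays.

    ``pairs[k] = (i, j)`` indexes left/right nodes; ``feats[k]`` holds
    (IoU, cosine, contour, shape) and ``mhd[k]`` the Mahalanobis distance
    under ``sigma``.  Directional edge features ``e_f``/``e_b`` (and their
    initial values ``e0_f``/``e0_b``) are (E, d_e) tensors; the two
    directions are distinct features.
    """

    left: list[CellInstance]
    right: list[CellInstance]
    v_left: np.ndarray
    v_right: np.ndarray
    pairs: np.ndarray                    # (E, 2) int
    feats: np.ndarray                    # (E, 4)
    mhd: np.ndarray                      # (E,)
    sigma: np.ndarray
    e0_f: Tensor | None = None
    e0_b: Tensor | None = None
    e_f: Tensor | None = None
    e_b: Tensor | None = None
    rounds_done: int = 0

    @property
    def edge_index(self) -> dict[tuple[int, int], int]:
        return {(int(i), int(j)): k for k, (i, j) in enumerate(self.pairs)}


def _node_features(instances: list[CellInstance], d_v: int) -> np.ndarray:
    from .simulate import _geometric_descriptor

    feats = []
    for inst in instances:
        if inst.appearance is not None and len(inst.appearance) == d_v:
            feats.append(np.asarray(inst.appearance, float))
        else:
            g = getattr(inst, "_geomdesc", None)
            if g is None:
                g = _geometric_descriptor(inst.contour)
                object.__setattr__(inst, "_geomdesc", g)
            if len(g) < d_v:
                g = np.pad(g, (0, d_v - len(g)))
            feats.append(g[:d_v])
    return np.array(feats).reshape(len(instances), d_v)


def _mhd_matrix(features: np.ndarray, mode: str) -> np.ndarray:
    """Quadratic-form matrix: inverse empirical node-feature covariance
    (standard Mahalanobis, default) or the literal covariance."""
    d = features.shape[1]
    if len(features) < 2:
        return np.eye(d)
    cov = np.atleast_2d(np.cov(features.T)) + 1e-6 * np.eye(d)
    if mode == "literal_sigma":
        return cov
    return np.linalg.inv(cov)


def _inst_cache(inst: CellInstance) -> dict:
    cache = getattr(inst, "_pairstats", None)
    if cache is None:
        cache = {
            "area": geometry.polygon_area(inst.contour),
            "ar": geometry.aspect_ratio(inst.contour),
        }
        object.__setattr__(inst, "_pairstats", cache)
    return cache


def pair_features(i_inst: CellInstance, j_inst: CellInstance) -> np.ndarray:
    """(IoU, cosine, contour similarity, shape similarity) of one pair.

    The shape-similarity term is the documented three-term sum (area ratio
    + aspect-ratio agreement + contour similarity); the contour term is
    computed once and shared with the third feature.
    """
    iou = geometry.polygon_iou(i_inst.contour, j_inst.contour)
    if i_inst.appearance is not None and j_inst.appearance is not None \
            and len(i_inst.appearance) == len(j_inst.appearance):
        cos = cosine_sim(i_inst.appearance, j_inst.appearance)
    else:
        cos = 0.0
    csim = geometry.contour_similarity(i_inst.contour, j_inst.contour)
    ca, cb = _inst_cache(i_inst), _inst_cache(j_inst)
    t_area = min(ca["area"], cb["area"]) / max(ca["area"], cb["area"]) \
        if max(ca["area"], cb["area"]) > 0 else 0.0
    ssim = t_area + (1.0 - abs(ca["ar"] - cb["ar"])) + csim
    return np.array([iou, cos, csim, ssim])


def init_edge(i_inst: CellInstance, j_inst: CellInstance, net: TrackerNet):
    """Directional initial edge features e0_ij, e0_ji of a single pair."""
    feats = pair_features(i_inst, j_inst)
    x = Tensor(feats[None, :3])
    return net.f_init(x) + net.dir_fwd, net.f_init(x) + net.dir_bwd, feats


@dataclass
class GraphStatics:
    """Geometry-derived quantities of one frame pair, reusable across
    training steps (they do not depend on the network weights)."""

    v_left: np.ndarray
    v_right: np.ndarray
    pairs: np.ndarray
    feats: np.ndarray
    mhd: np.ndarray
    sigma: np.ndarray


def graph_statics(prev: list[CellInstance], cur: list[CellInstance],
                  d_v: int, gate_radius: float | None = None,
                  mhd_matrix: str = "inverse_cov") -> GraphStatics:
    v_left = _node_features(prev, d_v)
    v_right = _node_features(cur, d_v)
    pooled = np.vstack([v_left, v_right]) if len(prev) + len(cur) else \
        np.zeros((0, d_v))
    sigma = _mhd_matrix(pooled, mhd_matrix)

    if gate_radius is None:
        diam = [2.0 * np.sqrt(max(inst.area, 1.0) / np.pi)
                for inst in list(prev) + list(cur)]
        gate_radius = 3.0 * (np.mean(diam) if diam else 30.0)

    cent_prev = [a.centroid for a in prev]
    cent_cur = [b.centroid for b in cur]
    pairs, feats, mhds = [], [], []
    for i, a in enumerate(prev):
        ca = cent_prev[i]
        for j, b in enumerate(cur):
            if np.linalg.norm(ca - cent_cur[j]) >= gate_radius:
                continue
            pairs.append((i, j))
            feats.append(pair_features(a, b))
            mhds.append(mahalanobis(v_left[i], v_right[j], sigma))
    return GraphStatics(
        v_left=v_left, v_right=v_right,
        pairs=np.array(pairs, dtype=int).reshape(-1, 2),
        feats=np.array(feats, dtype=float).reshape(-1, 4),
        mhd=np.array(mhds, dtype=float),
        sigma=sigma,
    )


def build_graph(prev: list[CellInstance], cur: list[CellInstance],
                net: TrackerNet, gate_radius: float | None = None,
                mhd_matrix: str = "inverse_cov",
                statics: GraphStatics | None = None) -> FrameGraph:
    """Construct the initial bipartite graph with gated candidate edges."""
    st = statics or graph_statics(prev, cur, net.d_v, gate_radius, mhd_matrix)
    g = FrameGraph(left=list(prev), right=list(cur),
                   v_left=st.v_left, v_right=st.v_right,
                   pairs=st.pairs, feats=st.feats, mhd=st.mhd, sigma=st.sigma)
    if len(st.pairs):
        base = net.f_init(Tensor(st.feats[:, :3]))
        g.e0_f = base + net.dir_fwd
        g.e0_b = base + net.dir_bwd
        g.e_f, g.e_b = g.e0_f, g.e0_b
    return g


def update_graph(g: FrameGraph, net: TrackerNet, rounds: int = 3) -> FrameGraph:
    """Run ``rounds`` of similarity-boosted message passing in place.

    Each round maps every directional edge through
    f_e(e0, e_prev, v_i, v_j, MhD, shape) with a tanh squash, then updates
    each node from the learned-map-then-sum of its incident edge features.
    ``rounds=0`` is the identity.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if g.e_f is None or len(g.pairs) == 0:
        g.rounds_done += rounds
        return g
    li, ri = g.pairs[:, 0], g.pairs[:, 1]
    extra = Tensor(np.column_stack([g.mhd, g.feats[:, 3]]))
    # incidence matrices turn edge aggregation into matmuls
    Ml = np.zeros((len(g.left), len(g.pairs)))
    Mr = np.zeros((len(g.right), len(g.pairs)))
    Ml[li, np.arange(len(g.pairs))] = 1.0
    Mr[ri, np.arange(len(g.pairs))] = 1.0
    Ml_t, Mr_t = Tensor(Ml), Tensor(Mr)

    vl, vr = Tensor(g.v_left.copy()), Tensor(g.v_right.copy())
    for _ in range(rounds):
        vl_e, vr_e = vl[li], vr[ri]
        e_f = net.f_e(nn.concat([g.e0_f, g.e_f, vl_e, vr_e, extra], axis=1)).tanh()
        e_b = net.f_e(nn.concat([g.e0_b, g.e_b, vl_e, vr_e, extra], axis=1)).tanh()
        g.e_f, g.e_b = e_f, e_b
        vl = (net.v_self(vl) + Ml_t @ net.v_agg(e_f)).tanh()
        vr = (net.v_self(vr) + Mr_t @ net.v_agg(e_b)).tanh()
        g.rounds_done += 1
    g.v_left, g.v_right = vl.data, vr.data
    return g


def edge_confidence(g: FrameGraph, net: TrackerNet) -> Tensor:
    """S_sim per edge: mean of the sigmoid-squashed direction scores, (E, 1)."""
    s_f = net.clas(g.e_f).sigmoid()
    s_b = net.clas(g.e_b).sigmoid()
    return (s_f + s_b) * 0.5


def all_confidences(g: FrameGraph, net: TrackerNet) -> dict[tuple[int, int], float]:
    if g.e_f is None or len(g.pairs) == 0:
        return {}
    s = edge_confidence(g, net).data.ravel()
    return {(int(i), int(j)): float(v) for (i, j), v in zip(g.pairs, s)}


def match(g: FrameGraph, net: TrackerNet, s_tau: float = 0.5,
          confidences: dict | None = None) -> MatchResult:
    """One-to-one assignment maximising total S_sim over edges above S_tau."""
    conf = confidences if confidences is not None else all_confidences(g, net)
    nl, nr = len(g.left), len(g.right)
    if nl == 0 or nr == 0 or not conf:
        return MatchResult(pairs=[], births=list(range(nr)),
                           deaths=list(range(nl)))
    n = max(nl, nr)
    W = np.zeros((n, n))
    for (i, j), s in conf.items():
        if s > s_tau:
            W[i, j] = s
    rows, cols = linear_sum_assignment(-W)
    pairs = [(int(i), int(j), float(W[i, j]))
             for i, j in zip(rows, cols)
             if i < nl and j < nr and W[i, j] > s_tau]
    matched_l = {p[0] for p in pairs}
    matched_r = {p[1] for p in pairs}
    return MatchResult(
        pairs=pairs,
        births=[j for j in range(nr) if j not in matched_r],
        deaths=[i for i in range(nl) if i not in matched_l],
    )


@dataclass
class TrackerParams:
    s_tau: float = 0.5
    top_k: int = 200
    max_gap: int = 3
    rounds: int = 3
    gate_radius: float | None = None
    mhd_matrix: str = "inverse_cov"


def link_tracks(frames: list[list[CellInstance]],
                params: TrackerParams | None = None,
                net: TrackerNet | None = None) -> list[Track]:
    """Link per-frame instances into identity-preserving tracks.

    Unmatched previous-frame cells become occluded and re-enter the next
    graph's left side with their last-seen features for up to ``max_gap``
    frames; beyond that they terminate.  Track ids are assigned in
    creation order and never reused.
    """
    if len(frames) < 1:
        raise ValueError("at least one frame required")
    params = params or TrackerParams()
    net = net or TrackerNet.default()

    tracks: list[Track] = []
    live: list[Track] = []
    next_id = 0

    for t, insts in enumerate(frames):
        cur = select_topk(insts, params.top_k) if insts else []
        matched_r: set[int] = set()
        matched_l: set[int] = set()
        if live and cur:
            left_insts = [tr.last()[1] for tr in live]
            g = build_graph(left_insts, cur, net,
                            gate_radius=params.gate_radius,
                            mhd_matrix=params.mhd_matrix)
            update_graph(g, net, rounds=params.rounds)
            res = match(g, net, s_tau=params.s_tau)
            for i, j, _s in res.pairs:
                tr = live[i]
                tr.observations.append((t, cur[j]))
                tr.state, tr.gap = "active", 0
                matched_r.add(j)
                matched_l.add(i)
        survivors = []
        for i, tr in enumerate(live):
            if i in matched_l:
                survivors.append(tr)
                continue
            tr.gap += 1
            if tr.gap > params.max_gap:
                tr.state = "terminated"
            else:
                tr.state = "occluded"
                survivors.append(tr)
        for j, inst in enumerate(cur):
            if j not in matched_r:
                tr = Track(track_id=next_id, observations=[(t, inst)])
                next_id += 1
                tracks.append(tr)
                survivors.append(tr)
        live = survivors
    return tracks


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _prepare_samples(sequences, d_v: int, params: TrackerParams):
    """Precompute graph statics and edge labels for every consecutive-frame
    pair; ``sequences`` is a list of (frames_of_instances, frames_of_gt_ids)."""
    out = []
    for frames, gt_ids in sequences:
        for t in range(1, len(frames)):
            prev, cur = frames[t - 1], frames[t]
            if not prev or not cur:
                continue
            st = graph_statics(prev, cur, d_v, params.gate_radius,
                               params.mhd_matrix)
            if len(st.pairs) == 0:
                continue
            labels = np.array([
                float(gt_ids[t - 1][i] == gt_ids[t][j]) for i, j in st.pairs
            ])
            out.append((prev, cur, st, labels))
    return out


def train_tracker(sequences, schedule=None, seed: int = 0,
                  net: TrackerNet | None = None, epochs: int = 30,
                  lr: float = 0.05, params: TrackerParams | None = None):
    """Fit the GNN with binary cross-entropy on edge labels derived from
    ground-truth identity correspondences.  Deterministic for a fixed seed.
    Returns ``(net, per_epoch_loss)``."""
    if not sequences:
        raise ValueError("no training sequences")
    params = params or TrackerParams()
    if schedule is not None:
        epochs = schedule.epochs
        lr = schedule.L0
    rng = np.random.default_rng(seed)
    net = net or TrackerNet(seed=seed)
    samples = _prepare_samples(sequences, net.d_v, params)
    if not samples:
        raise ValueError("no consecutive-frame samples in the data")
    opt = nn.Adam(net.parameters(), lr=lr)
    log = []
    for _epoch in range(epochs):
        order = rng.permutation(len(samples))
        total = 0.0
        for si in order:
            prev, cur, st, labels = samples[si]
            opt.zero_grad()
            g = build_graph(prev, cur, net, statics=st)
            update_graph(g, net, rounds=params.rounds)
            s = edge_confidence(g, net).reshape(-1)
            s = s * (1 - 2e-6) + 1e-6
            y = Tensor(labels)
            loss = -((s.log() * y + (1 - s).log() * (1 - y)).mean())
            loss.backward()
            opt.step()
            total += loss.item()
        log.append(total / len(samples))
    return net, log


def make_training_sequences(n_sequences: int = 20, n_frames: int = 8,
                            n_cells: int = 6, drop_prob: float = 0.1,
                            seed: int = 0):
    """Standard toy corpus for tracker training: short synthetic sequences
    with persistent identities and occasional detection drops."""
    from .simulate import SceneConfig, inject_occlusion, simulate_sequence

    sequences = []
    for s in range(n_sequences):
        cfg = SceneConfig(width=160, height=160, n_cells=n_cells,
                          duration=(n_frames - 1) * 10.0, frame_interval=10.0,
                          drop_prob=drop_prob, noise_sd=0.0,
                          seed=(seed * 10007 + s) % (2 ** 31))
        _, gt = simulate_sequence(cfg)
        dets, ids = inject_occlusion(gt, cfg,
                                     np.random.default_rng((seed * 99991 + s) % (2 ** 31)))
        sequences.append((dets, ids))
    return sequences


def train_toy_tracker(seed: int = 0, epochs: int = 30,
                      params: TrackerParams | None = None):
    """Train the GNN on the standard toy corpus (20 sequences, 30 epochs)."""
    seqs = make_training_sequences(seed=seed)
    return train_tracker(seqs, seed=seed, epochs=epochs, params=params)


def edge_accuracy(sequences, net: TrackerNet,
                  params: TrackerParams | None = None,
                  threshold: float = 0.5) -> float:
    """Fraction of gated candidate edges classified correctly at `threshold`."""
    params = params or TrackerParams()
    samples = _prepare_samples(sequences, net.d_v, params)
    correct = total = 0
    for prev, cur, st, labels in samples:
        g = build_graph(prev, cur, net, statics=st)
        update_graph(g, net, rounds=params.rounds)
        s = edge_confidence(g, net).data.ravel()
        correct += int(np.sum((s > threshold) == (labels > 0.5)))
        total += len(labels)
    return correct / total if total else float("nan")
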