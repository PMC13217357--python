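"""Graph construction, similarity-boosted updates, matching and lifecycle."""

import itertools

import numpy as np
import pytest

from dpetrack import simulate as dsim
from dpetrack import tracker as T
from dpetrack.geometry import Contour
from dpetrack.segmenter import CellInstance

from .conftest import regular_ngon


def _inst(center=(10.0, 10.0), radius=5.0, score=1.0, appearance=None, frame=0):
    return CellInstance(frame=frame, contour=regular_ngon(24, radius, center),
                        score=score, appearance=appearance)


class TestSelectTopK:
    def test_basic_sort(self):
        insts = [_inst(score=0.9), _inst(score=0.5), _inst(score=0.7)]
        out = T.select_topk(insts, 2)
        assert [i.score for i in out] == [0.9, 0.7]

    def test_k_larger_than_n(self):
        insts = [_inst(score=0.5), _inst(score=0.9)]
        assert len(T.select_topk(insts, 10)) == 2

    def test_tie_break_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        insts = [_inst(center=(10 + 20 * i, 10), radius=rng.uniform(3, 6),
                       score=round(rng.choice([0.5, 0.8]), 2))
                 for i in range(6)]
        k = 3
        out = T.select_topk(insts, k)
        oracle = sorted(range(6), key=lambda i: (-insts[i].score,
                                                 -insts[i].area, i))[:k]
        assert [id(o) for o in out] == [id(insts[i]) for i in oracle]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            T.select_topk([], 0)


class TestSimilarityPrimitives:
    def test_cosine_examples(self):
        assert T.cosine_sim([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert T.cosine_sim([1, 0], [0, 1]) == pytest.approx(0.0)
        assert T.cosine_sim([1, 0], [1, 1]) == pytest.approx(1 / np.sqrt(2),
                                                             abs=1e-9)

    def test_cosine_zero_vector(self):
        with pytest.warns(UserWarning):
            assert T.cosine_sim([0, 0], [1, 1]) == 0.0

    def test_mahalanobis_identity_is_euclidean(self):
        assert T.mahalanobis([0, 0], [3, 4], np.eye(2)) == pytest.approx(5.0,
                                                                         abs=1e-9)
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = rng.normal(size=4), rng.normal(size=4)
            assert T.mahalanobis(a, b, np.eye(4)) == pytest.approx(
                np.linalg.norm(a - b), abs=1e-12)

    def test_mahalanobis_examples(self):
        assert T.mahalanobis([0, 0], [0, 0], np.eye(2)) == 0.0
        assert T.mahalanobis([1, 0], [0, 0], np.diag([4.0, 1.0])) == \
            pytest.approx(2.0)

    def test_mahalanobis_invalid_matrix(self):
        with pytest.raises(ValueError):
            T.mahalanobis([1, 0], [0, 0], np.array([[1, 2], [3, 4.0]]))
        with pytest.raises(ValueError):
            T.mahalanobis([1, 0], [0, 0], np.array([[-1, 0], [0, -1.0]]))


class TestEdgeInit:
    def test_identity_f_on_identical_instances(self):
        net = T.TrackerNet(d_v=8, d_e=3, seed=0)
        net.f_init.W.data = np.eye(3)
        net.f_init.b.data = np.zeros(3)
        app = np.array([1.0, 0, 0, 0, 0, 0, 0, 0])
        a = _inst(appearance=app)
        b = _inst(appearance=app, frame=1)
        fwd, bwd, feats = T.init_edge(a, b, net)
        assert np.allclose(fwd.data.ravel(), [1, 1, 1], atol=1e-9)
        assert feats[:3] == pytest.approx([1, 1, 1], abs=1e-9)

    def test_disjoint_orthogonal_pair(self):
        net = T.TrackerNet(d_v=8, d_e=3, seed=0)
        net.f_init.W.data = np.eye(3)
        net.f_init.b.data = np.zeros(3)
        a = _inst(center=(10, 10), appearance=np.eye(8)[0])
        b = _inst(center=(40, 40), appearance=np.eye(8)[1], frame=1)
        fwd, _, feats = T.init_edge(a, b, net)
        assert feats[0] == 0.0                      # disjoint IoU
        assert feats[1] == pytest.approx(0.0)       # orthogonal appearance
        assert 0.0 < feats[2] <= 1.0                # contour term remains
        assert np.allclose(fwd.data.ravel(), feats[:3])

    def test_zero_weight_f_zero_edges(self):
        net = T.TrackerNet(d_v=8, d_e=4, seed=0)
        net.f_init.W.data[:] = 0.0
        net.f_init.b.data[:] = 0.0
        fwd, bwd, _ = T.init_edge(_inst(), _inst(frame=1), net)
        assert np.allclose(fwd.data, 0.0)
        assert np.allclose(bwd.data, 0.0)

    def test_directions_are_distinct_features(self):
        net = T.TrackerNet(d_v=8, d_e=4, seed=0)
        net.dir_fwd.data[:] = 0.5
        net.dir_bwd.data[:] = -0.5
        fwd, bwd, _ = T.init_edge(_inst(), _inst(frame=1), net)
        assert not np.allclose(fwd.data, bwd.data)


class TestUpdateGraph:
    def _two_cell_graph(self, net):
        prev = [_inst(center=(10, 10)), _inst(center=(40, 40))]
        cur = [_inst(center=(11, 10), frame=1), _inst(center=(41, 40), frame=1)]
        return T.build_graph(prev, cur, net)

    def test_zero_rounds_identity(self):
        net = T.TrackerNet(seed=0)
        g = self._two_cell_graph(net)
        e_before = g.e_f.data.copy()
        T.update_graph(g, net, rounds=0)
        assert np.array_equal(g.e_f.data, e_before)

    def test_fe_ignoring_all_but_e0(self):
        net = T.TrackerNet(d_v=8, d_e=3, seed=1)
        net.f_e.W.data[:] = 0.0
        net.f_e.W.data[:3, :3] = np.eye(3)          # read only the e0 slot
        net.f_e.b.data[:] = 0.0
        g = self._two_cell_graph(net)
        e0 = g.e0_f.data.copy()
        T.update_graph(g, net, rounds=3)
        assert np.allclose(g.e_f.data, np.tanh(e0), atol=1e-12)

    def test_two_rounds_match_manual_unroll(self):
        net = T.TrackerNet(d_v=3, d_e=2, seed=3)
        prev = [_inst(center=(10, 10), appearance=np.array([0.2, 0.5, 0.1]))]
        cur = [_inst(center=(12, 10), appearance=np.array([0.3, 0.4, 0.2]),
                     frame=1)]
        g = T.build_graph(prev, cur, net)
        e0f, e0b = g.e0_f.data.copy(), g.e0_b.data.copy()
        vl, vr = g.v_left.copy(), g.v_right.copy()
        extra = np.array([[g.mhd[0], g.feats[0, 3]]])
        Wf, bf = net.f_e.W.data, net.f_e.b.data
        Ws, bs = net.v_self.W.data, net.v_self.b.data
        Wa, ba = net.v_agg.W.data, net.v_agg.b.data
        ef, eb = e0f, e0b
        for _ in range(2):
            ef = np.tanh(np.hstack([e0f, ef, vl, vr, extra]) @ Wf + bf)
            eb = np.tanh(np.hstack([e0b, eb, vl, vr, extra]) @ Wf + bf)
            vl = np.tanh(vl @ Ws + bs + (ef @ Wa + ba))
            vr = np.tanh(vr @ Ws + bs + (eb @ Wa + ba))
        T.update_graph(g, net, rounds=2)
        assert np.allclose(g.e_f.data, ef, atol=1e-6)
        assert np.allclose(g.e_b.data, eb, atol=1e-6)
        assert np.allclose(g.v_left, vl, atol=1e-6)

    def test_negative_rounds_rejected(self):
        net = T.TrackerNet(seed=0)
        with pytest.raises(ValueError):
            T.update_graph(self._two_cell_graph(net), net, rounds=-1)


class TestEdgeConfidence:
    def test_zero_weight_head_gives_half(self):
        net = T.TrackerNet(seed=0)
        net.clas.W.data[:] = 0.0
        net.clas.b.data[:] = 0.0
        prev, cur = [_inst()], [_inst(center=(11, 10), frame=1)]
        g = T.build_graph(prev, cur, net)
        T.update_graph(g, net, rounds=1)
        conf = T.all_confidences(g, net)
        assert all(v == pytest.approx(0.5) for v in conf.values())

    def test_direction_swap_symmetric(self):
        net = T.TrackerNet.default()
        prev, cur = [_inst()], [_inst(center=(12, 11), frame=1)]
        g = T.build_graph(prev, cur, net)
        T.update_graph(g, net, rounds=2)
        s = T.edge_confidence(g, net).data
        swapped = T.FrameGraph(left=g.left, right=g.right, v_left=g.v_left,
                               v_right=g.v_right, pairs=g.pairs, feats=g.feats,
                               mhd=g.mhd, sigma=g.sigma,
                               e0_f=g.e0_b, e0_b=g.e0_f,
                               e_f=g.e_b, e_b=g.e_f)
        s2 = T.edge_confidence(swapped, net).data
        assert np.allclose(s, s2)

    def test_monotone_in_iou_for_default_net(self):
        net = T.TrackerNet.default()
        scores = []
        for dx in (0.0, 1.0, 2.5, 4.0):
            prev, cur = [_inst()], [_inst(center=(10 + dx, 10), frame=1)]
            g = T.build_graph(prev, cur, net)
            T.update_graph(g, net, rounds=2)
            scores.append(float(T.edge_confidence(g, net).data.ravel()[0]))
        assert all(a >= b for a, b in zip(scores, scores[1:]))


def _graph_from_scores(scores: np.ndarray) -> tuple:
    """Build a FrameGraph stub plus confidence dict from a score matrix."""
    nl, nr = scores.shape
    prev = [_inst(center=(10 + 30 * i, 10)) for i in range(nl)]
    cur = [_inst(center=(10 + 30 * j, 12), frame=1) for j in range(nr)]
    g = T.FrameGraph(left=prev, right=cur, v_left=np.zeros((nl, 8)),
                     v_right=np.zeros((nr, 8)),
                     pairs=np.array([(i, j) for i in range(nl)
                                     for j in range(nr)]),
                     feats=np.zeros((nl * nr, 4)), mhd=np.zeros(nl * nr),
                     sigma=np.eye(8))
    conf = {(i, j): float(scores[i, j]) for i in range(nl) for j in range(nr)}
    return g, conf


def _bruteforce_match(scores: np.ndarray, s_tau: float):
    """Exhaustive best one-to-one assignment over edges above threshold."""
    nl, nr = scores.shape
    best, best_pairs = 0.0, []
    left = list(range(nl))
    for k in range(min(nl, nr) + 1):
        for ls in itertools.combinations(left, k):
            for rs in itertools.permutations(range(nr), k):
                if any(scores[i, j] <= s_tau for i, j in zip(ls, rs)):
                    continue
                tot = sum(scores[i, j] for i, j in zip(ls, rs))
                if tot > best + 1e-12:
                    best, best_pairs = tot, sorted(zip(ls, rs))
    return best, best_pairs


class TestMatch:
    def test_2x2_example(self):
        g, conf = _graph_from_scores(np.array([[0.9, 0.2], [0.3, 0.8]]))
        res = T.match(g, T.TrackerNet.default(), s_tau=0.5, confidences=conf)
        assert sorted((i, j) for i, j, _ in res.pairs) == [(0, 0), (1, 1)]

    def test_all_below_threshold(self):
        g, conf = _graph_from_scores(np.full((2, 3), 0.3))
        res = T.match(g, T.TrackerNet.default(), s_tau=0.5, confidences=conf)
        assert res.pairs == []
        assert res.births == [0, 1, 2]
        assert res.deaths == [0, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_3x3_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random((3, 3))
        g, conf = _graph_from_scores(scores)
        res = T.match(g, T.TrackerNet.default(), s_tau=0.5, confidences=conf)
        total = sum(s for _, _, s in res.pairs)
        best, best_pairs = _bruteforce_match(scores, 0.5)
        assert total == pytest.approx(best, abs=1e-9)
        assert sorted((i, j) for i, j, _ in res.pairs) == best_pairs


class TestLinkTracks:
    def test_single_static_cell(self):
        frames = [[_inst(frame=t)] for t in range(10)]
        tracks = T.link_tracks(frames)
        assert len(tracks) == 1
        assert len(tracks[0].observations) == 10

    def test_gap_shorter_than_max_gap_preserves_identity(self):
        frames = []
        for t in range(10):
            if t in (5, 6):
                frames.append([])
            else:
                frames.append([_inst(center=(20 + 1.0 * t, 20), frame=t)])
        tracks = T.link_tracks(frames, params=T.TrackerParams(max_gap=3))
        assert len(tracks) == 1
        obs_frames = [f for f, _ in tracks[0].observations]
        assert obs_frames == [0, 1, 2, 3, 4, 7, 8, 9]

    def test_gap_longer_than_max_gap_terminates(self):
        frames = []
        for t in range(12):
            frames.append([] if 3 <= t <= 7 else
                          [_inst(center=(20, 20), frame=t)])
        tracks = T.link_tracks(frames, params=T.TrackerParams(max_gap=3))
        assert len(tracks) == 2

    def test_two_distant_crossing_cells_keep_identity(self):
        frames = []
        app_a, app_b = np.eye(8)[0], np.eye(8)[1]
        for t in range(9):
            a = _inst(center=(20 + 4 * t, 20), radius=6, appearance=app_a,
                      frame=t)
            b = _inst(center=(52 - 4 * t, 70), radius=6, appearance=app_b,
                      frame=t)
            frames.append([a, b])
        tracks = T.link_tracks(frames, params=T.TrackerParams())
        assert len(tracks) == 2
        for tr in tracks:
            apps = [inst.appearance for _, inst in tr.observations]
            assert all(np.array_equal(apps[0], a) for a in apps)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            T.link_tracks([])

    def test_ids_never_reused(self):
        frames = [[_inst(center=(20, 20), frame=0)], [],
                  [], [], [],
                  [_inst(center=(20, 20), frame=5)]]
        tracks = T.link_tracks(frames, params=T.TrackerParams(max_gap=2))
        ids = [tr.track_id for tr in tracks]
        assert len(ids) == len(set(ids)) == 2


class TestTraining:
    @pytest.fixture(scope="class")
    def toy_sequences(self):
        return T.make_training_sequences(n_sequences=4, n_frames=5,
                                         n_cells=4, seed=0)

    def test_zero_lr_unchanged(self, toy_sequences):
        net = T.TrackerNet(seed=0)
        before = {k: v.copy() for k, v in net.named_arrays().items()}
        net, _ = T.train_tracker(toy_sequences, net=net, epochs=1, lr=0.0,
                                 seed=0)
        for k, v in net.named_arrays().items():
            assert np.array_equal(before[k], v), k

    def test_deterministic_given_seed(self, toy_sequences):
        n1, log1 = T.train_tracker(toy_sequences, epochs=2, seed=4)
        n2, log2 = T.train_tracker(toy_sequences, epochs=2, seed=4)
        assert log1 == log2
        for k, v in n1.named_arrays().items():
            assert np.array_equal(v, n2.named_arrays()[k])

    def test_label_permutation_control_is_chance_level(self, toy_sequences):
        """Training on shuffled labels must not beat chance on balanced
        held-out edges."""
        rng = np.random.default_rng(0)
        shuffled = []
        for prev_frames, ids in toy_sequences:
            perm_ids = [list(rng.permutation(f_ids)) for f_ids in ids]
            shuffled.append((prev_frames, perm_ids))
        net, _ = T.train_tracker(shuffled, epochs=5, seed=0)
        held = T.make_training_sequences(n_sequences=3, n_frames=5,
                                         n_cells=4, seed=77)
        params = T.TrackerParams()
        correct = total = 0
        for frames, gt_ids in held:
            samples = T._prepare_samples([(frames, gt_ids)], net.d_v, params)
            for prev, cur, st, labels in samples:
                g = T.build_graph(prev, cur, net, statics=st)
                T.update_graph(g, net, rounds=params.rounds)
                s = T.edge_confidence(g, net).data.ravel()
                pos = np.flatnonzero(labels > 0.5)
                neg = np.flatnonzero(labels <= 0.5)
                n = min(len(pos), len(neg))
                for k in list(pos[:n]) + list(neg[:n]):
                    correct += int((s[k] > 0.5) == (labels[k] > 0.5))
                    total += 1
        assert total > 50
        assert correct / total == pytest.approx(0.5, abs=0.1)

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            T.train_tracker([], epochs=1)
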