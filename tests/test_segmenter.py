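"""Detection decoding, contour initialisation, offset heads, landmarks,
profile evolution, postprocessing and the training schedule."""

import numpy as np
import pytest

from dpetrack import geometry as G
from dpetrack.segmenter import (
    CellInstance,
    Landmarks,
    Segmenter,
    SegmenterNet,
    TrainingSchedule,
    bfe_offsets,
    boxes_iou,
    chain_direction_onehot,
    decode_detections,
    dpe_evolve,
    extract_landmarks,
    init_contour,
    lr_at_epoch,
    mlp_offsets,
    postprocess,
    train_segmenter,
)
from dpetrack.geometry import Contour

from .conftest import make_training_frames, regular_ngon


@pytest.fixture(scope="module")
def tiny_net():
    return SegmenterNet(channels=(8, 16, 32), n_vertices=32, seed=0)


def _zero_heads(net):
    for p in (net.bfe_h, net.bfe_o, net.mlp_c, net.mlp_o):
        p.W.data[:] = 0.0
        p.b.data[:] = 0.0


class TestDetect:
    def test_empty_heatmap(self):
        dets = decode_detections(np.zeros((16, 16)), np.zeros((2, 16, 16)),
                                 stride=4, score_thr=0.3)
        assert dets == []

    def test_single_gaussian_peak(self):
        yy, xx = np.mgrid[0:24, 0:24]
        heat = 0.9 * np.exp(-((xx - 10) ** 2 + (yy - 7) ** 2) / 8.0)
        size = np.full((2, 24, 24), np.log(12.0))
        dets = decode_detections(heat, size, stride=4, score_thr=0.3)
        assert len(dets) == 1
        (bbox, center, score) = dets[0]
        assert center == pytest.approx(((10 + 0.5) * 4, (7 + 0.5) * 4), abs=4)
        assert score == pytest.approx(0.9, abs=1e-6)
        assert bbox[2] == pytest.approx(12.0)

    def test_nms_keeps_higher_score(self):
        heat = np.zeros((24, 24))
        heat[10, 10], heat[10, 11] = 0.8, 0.6
        size = np.full((2, 24, 24), np.log(20.0))
        dets = decode_detections(heat, size, stride=4, score_thr=0.3,
                                 nms_iou=0.5, min_distance=1)
        assert len(dets) == 1
        assert dets[0][2] == pytest.approx(0.8)

    def test_boxes_iou(self):
        assert boxes_iou((0, 0, 2, 2), (1, 0, 2, 2)) == pytest.approx(1 / 3)
        assert boxes_iou((0, 0, 1, 1), (5, 5, 1, 1)) == 0.0


class TestInitContour:
    def test_square_bbox_gives_circle(self):
        c = init_contour((0, 0, 10, 10), 64)
        r = np.hypot(*(c.vertices - [5, 5]).T)
        assert np.allclose(r, 5.0, atol=1e-9)
        assert G.signed_area(c) > 0

    def test_axes_ratio(self):
        c = init_contour((0, 0, 20, 10), 256)
        major, minor = G.min_rect_sides(c)
        assert major / minor == pytest.approx(2.0, abs=1e-3)

    def test_arc_spacing_mild_eccentricity(self):
        c = init_contour((0, 0, 11, 10), 64)
        seg = np.hypot(*np.diff(np.vstack([c.vertices, c.vertices[:1]]),
                                axis=0).T)
        assert seg.std() / seg.mean() < 0.05

    def test_degenerate_box(self):
        with pytest.raises(ValueError):
            init_contour((0, 0, 0, 5), 32)
        with pytest.raises(ValueError):
            init_contour((0, 0, 5, 5), 4)


class TestOffsetHeads:
    def test_zero_weights_identity(self, tiny_net, star_scene):
        _zero_heads(tiny_net)
        pyr = tiny_net.backbone(star_scene["image"])
        c0 = init_contour((30, 30, 30, 30), tiny_net.n_vertices)
        c1 = bfe_offsets(c0, pyr, tiny_net)
        assert np.allclose(c1.vertices, c0.vertices)
        c2 = mlp_offsets(c0, pyr, tiny_net, passes=2)
        assert np.allclose(c2.vertices, c0.vertices)

    def test_offsets_bounded_by_r_max(self, star_scene):
        net = SegmenterNet(channels=(8, 16, 32), n_vertices=32, r_max=2.5, seed=1)
        # blow up the head weights: outputs must stay inside tanh * r_max
        net.bfe_o.W.data = np.random.default_rng(0).normal(0, 50, net.bfe_o.W.data.shape)
        pyr = net.backbone(star_scene["image"])
        c0 = init_contour((30, 30, 30, 30), net.n_vertices)
        c1 = bfe_offsets(c0, pyr, net)
        assert np.abs(c1.vertices - c0.vertices).max() <= 2.5 + 1e-9

    def test_chain_code_onehot(self):
        c = Contour.from_vertices([(0, 0), (4, 0), (4, 4), (0, 4)])
        oh = chain_direction_onehot(c)
        codes = np.argmax(oh, axis=1)
        # east, up-the-screen? square CCW in image coords: E, S(+y)=6, W, N
        assert oh.shape == (4, 8)
        assert set(codes) == {0, 6, 4, 2}

    def test_mlp_gradients_reach_every_vertex(self, star_scene):
        net = SegmenterNet(channels=(8, 16, 32), n_vertices=24, seed=2)
        # the output layer starts at zero (identity head); give it weights
        # so gradient flow through the whole stack is observable
        net.mlp_o.W.data = np.random.default_rng(0).normal(
            0, 0.3, net.mlp_o.W.data.shape)
        pyr = net.backbone(star_scene["image"])
        c0 = init_contour((30, 30, 30, 30), 24)
        off = mlp_offsets(c0, pyr, net, passes=1, train=True)
        assert off.data.shape == (24, 2)
        assert np.abs(off.data).sum() > 0
        (off * off).sum().backward()
        assert net.mlp_c.W.grad is not None
        assert np.abs(net.mlp_c.W.grad).sum() > 0
        assert np.abs(net.mlp_o.W.grad).sum() > 0

    def test_two_passes_with_zero_weights_equals_one(self, star_scene):
        # zero weights make every pass the identity, so pass count is moot
        net = SegmenterNet(channels=(8, 16, 32), n_vertices=16, seed=3)
        _zero_heads(net)
        pyr = net.backbone(star_scene["image"])
        c0 = init_contour((30, 30, 20, 20), 16)
        one = mlp_offsets(c0, pyr, net, passes=1)
        two = mlp_offsets(c0, pyr, net, passes=2)
        assert np.allclose(one.vertices, two.vertices)


class TestLandmarks:
    def test_star_tips_found(self, star_scene):
        lms = extract_landmarks(star_scene["image"], star_scene["contour"])
        d = np.linalg.norm(
            lms.points[:, None, :] - star_scene["tips"][None], axis=2)
        assert (d.min(axis=0) <= 2.0).all()
        assert len(lms.points) >= 5

    def test_disk_landmarks_on_rim(self):
        from dpetrack import simulate as dsim

        cfg = dsim.SceneConfig(width=64, height=64, noise_sd=0.0, duration=0)
        disk = regular_ngon(96, radius=12, center=(32, 32))
        img = dsim._render_frame(cfg, [disk.vertices],
                                 np.random.default_rng(0)).astype(float) / 255.0
        lms = extract_landmarks(img, disk)
        r = np.hypot(*(lms.points - [32, 32]).T)
        assert np.all(np.abs(r - 12) <= 2.0)

    def test_blank_patch_falls_back(self):
        c = regular_ngon(16, radius=5, center=(16, 16))
        lms = extract_landmarks(np.full((32, 32), 0.5), c)
        assert len(lms.points) >= 1
        assert np.all(lms.weights >= 0)


class TestDPE:
    def test_fixed_point_when_landmarks_on_vertices(self):
        c = regular_ngon(32, radius=8, center=(24, 24))
        lms = Landmarks(points=c.vertices.copy(), weights=np.ones(32))
        flat = np.full((48, 48), 0.5)
        out, iters = dpe_evolve(c, lms, flat, max_iter=10, tol=0.05)
        assert iters == 1
        assert np.allclose(out.vertices, G.resample_contour(c, 32).vertices,
                           atol=1e-6)

    def test_star_recovery_from_inner_circle(self, star_scene):
        circ = init_contour((42, 42, 12, 12), 128)
        lms = Landmarks(points=star_scene["tips"], weights=np.ones(5))
        log = []
        out, iters = dpe_evolve(circ, lms, star_scene["image"],
                                max_iter=50, tol=0.05, log=log)
        assert G.polygon_iou(out, star_scene["contour"]) >= 0.90
        for tip in star_scene["tips"]:
            assert np.min(np.linalg.norm(out.vertices - tip, axis=1)) <= 3.0
        tail = log[-5:]
        assert all(a >= b - 1e-12 for a, b in zip(tail, tail[1:]))

    def test_output_always_simple(self, star_scene):
        rng = np.random.default_rng(0)
        for k in range(20):
            x0, y0 = rng.uniform(30, 55, 2)
            c = init_contour((x0, y0, rng.uniform(8, 25), rng.uniform(8, 25)), 64)
            lms = Landmarks(points=star_scene["tips"],
                            weights=rng.uniform(0.5, 1, 5))
            out, _ = dpe_evolve(c, lms, star_scene["image"], max_iter=30,
                                tol=0.05)
            assert G.is_simple(out)

    def test_parameter_validation(self, star_scene):
        c = init_contour((40, 40, 10, 10), 32)
        lms = Landmarks(points=[[48, 48]], weights=[1.0])
        with pytest.raises(ValueError):
            dpe_evolve(c, lms, star_scene["image"], max_iter=0)
        with pytest.raises(ValueError):
            dpe_evolve(c, lms, star_scene["image"], tol=0.0)


class TestPostprocess:
    def _inst(self, contour, score, frame=0):
        return CellInstance(frame=frame, contour=contour, score=score)

    def test_noop_settings_identity(self):
        insts = [self._inst(regular_ngon(20, 5, (10, 10)), 0.9)]
        out = postprocess(insts, min_area=0, smooth_window=1, dedup_iou=1.0)
        assert len(out) == 1
        assert np.allclose(out[0].contour.vertices, insts[0].contour.vertices)

    def test_dedup_keeps_higher_score(self):
        a = self._inst(regular_ngon(20, 5, (10, 10)), 0.9)
        b = self._inst(regular_ngon(20, 5.05, (10, 10)), 0.7)
        out = postprocess([a, b], min_area=0, smooth_window=1, dedup_iou=0.9)
        assert len(out) == 1
        assert out[0].score == 0.9

    def test_smoothing_raises_circularity_of_spiky_contour(self, star_scene):
        spiky = self._inst(star_scene["contour"], 0.9)
        before = G.circularity(spiky.contour)
        out = postprocess([spiky], min_area=0, smooth_window=7, dedup_iou=1.0)
        assert G.circularity(out[0].contour) > before

    def test_min_area_filter(self):
        small = self._inst(regular_ngon(12, 1.2, (5, 5)), 0.9)   # ~4.4 px^2
        big = self._inst(regular_ngon(12, 4.0, (20, 20)), 0.8)   # ~49 px^2
        out = postprocess([small, big], min_area=10, smooth_window=1)
        assert [i.score for i in out] == [0.8]


class TestLearningRateSchedule:
    def test_initial_rate(self):
        s = TrainingSchedule()
        assert lr_at_epoch(s, 0) == pytest.approx(1e-5)

    def test_gamma_one_constant(self):
        s = TrainingSchedule(L0=1e-3, gamma=1.0, decay_every=50, epochs=10)
        assert lr_at_epoch(s, 199) == pytest.approx(1e-3)

    def test_closed_form_epoch_120(self):
        s = TrainingSchedule(L0=1e-5, gamma=0.1, decay_every=50)
        assert lr_at_epoch(s, 120) == pytest.approx(1e-7)

    def test_matches_iterative_decay_200_epochs(self):
        s = TrainingSchedule(L0=1e-5, gamma=0.1, decay_every=50, epochs=200)
        L = s.L0
        for epoch in range(200):
            assert lr_at_epoch(s, epoch) == pytest.approx(L, rel=1e-12)
            if (epoch + 1) % s.decay_every == 0:
                L = L * s.gamma

    def test_negative_epoch(self):
        with pytest.raises(ValueError):
            lr_at_epoch(TrainingSchedule(), -1)


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_dataset(self):
        return make_training_frames(4, 7000, n_cells=3, size=96)

    def test_zero_lr_leaves_weights_unchanged(self, tiny_dataset):
        net = SegmenterNet(channels=(8, 16, 32), n_vertices=16, seed=0)
        before = {k: v.copy() for k, v in net.named_arrays().items()}
        sched = TrainingSchedule(L0=0.0, gamma=1.0, decay_every=1, epochs=1,
                                 batch_size=2, dropout_p=0.0)
        net, _ = train_segmenter(tiny_dataset, sched, seed=0, net=net)
        after = net.named_arrays()
        for k in before:
            assert np.array_equal(before[k], after[k]), k

    def test_identical_seeds_identical_loss_curves(self, tiny_dataset):
        sched = TrainingSchedule(L0=1e-3, gamma=0.5, decay_every=2, epochs=2,
                                 batch_size=2)
        _, log1 = train_segmenter(tiny_dataset, sched, seed=5)
        _, log2 = train_segmenter(tiny_dataset, sched, seed=5)
        assert log1 == log2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter([], TrainingSchedule(), seed=0)

    def test_loss_decreases(self, tiny_dataset):
        sched = TrainingSchedule(L0=3e-3, gamma=0.5, decay_every=4, epochs=6,
                                 batch_size=2)
        _, log = train_segmenter(tiny_dataset, sched, seed=0)
        assert log[-1] < 0.5 * log[0]


def test_ablation_identity_reduces_to_init_contour(star_scene):
    """With every learnable offset zeroed and DPE disabled, the pipeline is
    init_contour followed by postprocessing."""
    net = SegmenterNet(channels=(8, 16, 32), n_vertices=32, seed=0)
    _zero_heads(net)
    pyr = net.backbone(star_scene["image"])
    bbox = (40, 40, 16, 16)
    c0 = init_contour(bbox, 32)
    c1 = bfe_offsets(c0, pyr, net)
    c2 = mlp_offsets(c1, pyr, net, passes=1)
    out = postprocess([CellInstance(frame=0, contour=c2, score=1.0)],
                      min_area=0, smooth_window=1, dedup_iou=1.0)
    assert np.allclose(out[0].contour.vertices, c0.vertices)
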