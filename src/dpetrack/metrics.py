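"""Detection and tracking evaluation.

Detection follows the COCO convention: greedy score-ordered matching at
each IoU threshold, 101-point interpolated average precision, average
recall as the mean best recall over the threshold grid 0.50:0.05:0.95,
and area classes small (< 32^2 px^2), mid (32^2..96^2) and large (> 96^2).

Tracking follows the CLEAR-MOT convention: per-frame correspondences that
persist across frames when still valid, MOTA = 1 - (FN + FP + IDS) / GT,
identity switches counted on ground-truth reassignments, and IDF1 from a
global min-cost identity matching between predicted and true tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import geometry
from .geometry import Contour

__all__ = [
    "DetectionEval",
    "TrackingEval",
    "average_precision",
    "detection_eval",
    "clear_mot",
    "AREA_SMALL",
    "AREA_MID",
]

AREA_SMALL = 32.0 ** 2
AREA_MID = 96.0 ** 2
IOU_GRID = np.round(np.arange(0.50, 0.96, 0.05), 2)


@dataclass
class DetectionEval:
    ap: float
    ap50: float
    ar: float
    ar_small: float
    ar_mid: float
    ar_large: float
    precision: dict = field(default_factory=dict)   # iou_thr -> array
    recall: dict = field(default_factory=dict)


@dataclass
class TrackingEval:
    mota: float
    idf1: float
    ids: int
    fp: int
    fn: int
    n_gt: int
    n_matches: int


def _group_by_frame(items):
    frames: dict[int, list] = {}
    for it in items:
        frames.setdefault(it.frame, []).append(it)
    return frames


def _match_greedy(dets, gts, iou_thr: float):
    """Score-ordered greedy matching of one frame; returns per-det tp flags
    and the matched-gt count.  ``dets`` must already be score-sorted."""
    matched = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for di, d in enumerate(dets):
        best, best_iou = -1, iou_thr
        for gi, g in enumerate(gts):
            if matched[gi]:
                continue
            iou = geometry.polygon_iou(d.contour, g.contour)
            if iou >= best_iou:
                best, best_iou = gi, iou
        if best >= 0:
            matched[best] = True
            tp[di] = True
    return tp, int(matched.sum())


def _ap_101(tp: np.ndarray, n_gt: int) -> tuple[float, np.ndarray, np.ndarray]:
    """101-point interpolated AP from score-ordered true-positive flags."""
    if n_gt == 0:
        return float("nan"), np.array([]), np.array([])
    if len(tp) == 0:
        return 0.0, np.array([]), np.array([])
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope, then sample on the 101-point recall grid
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    grid = np.linspace(0, 1, 101)
    interp = np.zeros(101)
    for k, r in enumerate(grid):
        idx = np.searchsorted(recall, r, side="left")
        interp[k] = prec_env[idx] if idx < len(prec_env) else 0.0
    return float(interp.mean()), precision, recall


def average_precision(dets, gts, iou_thresholds=None,
                      area_range: tuple[float, float] | None = None) -> DetectionEval:
    """COCO-style detection evaluation of polygon instances.

    ``dets`` and ``gts`` are flat lists of objects with ``frame``,
    ``contour`` and (for dets) ``score``.  GT outside ``area_range`` is
    ignored: detections matching an ignored GT are neither TP nor FP.
    """
    thrs = IOU_GRID if iou_thresholds is None else np.atleast_1d(iou_thresholds)
    det_frames = _group_by_frame(dets)
    gt_frames = _group_by_frame(gts)
    all_frames = sorted(set(det_frames) | set(gt_frames))

    ap_per_thr, recall_per_thr = [], []
    prec_curves, rec_curves = {}, {}
    recalls_by_class = {"small": [], "mid": [], "large": []}

    for thr in thrs:
        flags, scores = [], []
        n_gt = 0
        class_tot = {"small": 0, "mid": 0, "large": 0}
        class_hit = {"small": 0, "mid": 0, "large": 0}
        for f in all_frames:
            dlist = sorted(det_frames.get(f, []), key=lambda d: -d.score)
            glist = gt_frames.get(f, [])
            areas = np.array([geometry.polygon_area(g.contour) for g in glist]) \
                if glist else np.array([])
            if area_range is not None and glist:
                in_range = (areas >= area_range[0]) & (areas < area_range[1])
            else:
                in_range = np.ones(len(glist), dtype=bool)
            eval_gts = [g for g, ok in zip(glist, in_range) if ok]
            ign_gts = [g for g, ok in zip(glist, in_range) if not ok]
            n_gt += len(eval_gts)
            tp, _ = _match_greedy(dlist, eval_gts, thr)
            # drop detections overlapping ignored GT from the FP count
            keep = np.ones(len(dlist), dtype=bool)
            for di, d in enumerate(dlist):
                if tp[di]:
                    continue
                if any(geometry.polygon_iou(d.contour, g.contour) >= thr
                       for g in ign_gts):
                    keep[di] = False
            flags.extend(tp[keep])
            scores.extend(d.score for d, k in zip(dlist, keep) if k)
            # area-class recall bookkeeping
            for cls, lo, hi in (("small", 0.0, AREA_SMALL),
                                ("mid", AREA_SMALL, AREA_MID),
                                ("large", AREA_MID, np.inf)):
                cls_gts = [g for g, a in zip(glist, areas) if lo <= a < hi]
                if not cls_gts:
                    continue
                _, n_hit = _match_greedy(dlist, cls_gts, thr)
                class_tot[cls] += len(cls_gts)
                class_hit[cls] += n_hit
        order = np.argsort(-np.asarray(scores)) if scores else np.array([], int)
        tp_sorted = np.asarray(flags, dtype=bool)[order]
        ap, prec, rec = _ap_101(tp_sorted, n_gt)
        ap_per_thr.append(ap)
        recall_per_thr.append(tp_sorted.sum() / n_gt if n_gt else float("nan"))
        prec_curves[float(thr)] = prec
        rec_curves[float(thr)] = rec
        for cls in recalls_by_class:
            if class_tot[cls]:
                recalls_by_class[cls].append(class_hit[cls] / class_tot[cls])

    def _mean(vals):
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    ap50 = ap_per_thr[int(np.argmin(np.abs(thrs - 0.5)))]
    return DetectionEval(
        ap=_mean(ap_per_thr), ap50=float(ap50), ar=_mean(recall_per_thr),
        ar_small=_mean(recalls_by_class["small"]),
        ar_mid=_mean(recalls_by_class["mid"]),
        ar_large=_mean(recalls_by_class["large"]),
        precision=prec_curves, recall=rec_curves,
    )


detection_eval = average_precision


# ---------------------------------------------------------------------------
# CLEAR-MOT / IDF1
# ---------------------------------------------------------------------------

def _as_frame_dict(tracks):
    """Normalise track input to {frame: {track_id: Contour | (x, y)}}.

    Accepts that mapping directly, a list of Track objects, or a DataFrame
    with frame/track_id/x/y columns.
    """
    if isinstance(tracks, dict):
        return tracks
    if hasattr(tracks, "columns"):
        out: dict[int, dict] = {}
        xcol = "x_centroid" if "x_centroid" in tracks.columns else "x"
        ycol = "y_centroid" if "y_centroid" in tracks.columns else "y"
        for row in tracks.itertuples(index=False):
            f, tid = int(getattr(row, "frame")), int(getattr(row, "track_id"))
            out.setdefault(f, {})[tid] = (float(getattr(row, xcol)),
                                          float(getattr(row, ycol)))
        return out
    out = {}
    for tr in tracks:
        for f, inst in tr.observations:
            out.setdefault(f, {})[tr.track_id] = inst.contour
    return out


def _pair_affinity(a, b, iou_thr: float, dist_thr: float):
    """Affinity in [0, 1] of one pred/gt entry pair, or None if no match.

    Polygon pairs use IoU >= iou_thr; point pairs (or mixed) fall back to
    centroid distance < dist_thr.
    """
    poly_a, poly_b = isinstance(a, Contour), isinstance(b, Contour)
    if poly_a and poly_b:
        iou = geometry.polygon_iou(a, b)
        return iou if iou >= iou_thr else None
    ca = geometry.polygon_centroid(a) if poly_a else np.asarray(a, float)
    cb = geometry.polygon_centroid(b) if poly_b else np.asarray(b, float)
    d = float(np.linalg.norm(ca - cb))
    return 1.0 - d / dist_thr if d < dist_thr else None


def clear_mot(tracks, gt_tracks, iou_match_thr: float = 0.5,
              dist_thr: float = 10.0) -> TrackingEval:
    """CLEAR-MOT metrics plus IDF1 against ground-truth tracks."""
    pred = _as_frame_dict(tracks)
    gt = _as_frame_dict(gt_tracks)
    frames = sorted(set(pred) | set(gt))

    fp = fn = ids = n_gt = n_match = 0
    last_match: dict = {}                 # gt id -> last matched pred id
    # identity co-occurrence counts for IDF1
    co: dict[tuple, int] = {}
    gt_obs: dict = {}
    pred_obs: dict = {}

    for f in frames:
        p = pred.get(f, {})
        g = gt.get(f, {})
        n_gt += len(g)
        for gid in g:
            gt_obs[gid] = gt_obs.get(gid, 0) + 1
        for pid in p:
            pred_obs[pid] = pred_obs.get(pid, 0) + 1

        gids, pids = list(g), list(p)
        matches: dict = {}
        # persist previous correspondences still valid at this frame
        for gid in gids:
            pid = last_match.get(gid)
            if pid is not None and pid in p and pid not in matches.values():
                aff = _pair_affinity(p[pid], g[gid], iou_match_thr, dist_thr)
                if aff is not None:
                    matches[gid] = pid
        # Hungarian on the remainder
        free_g = [gid for gid in gids if gid not in matches]
        free_p = [pid for pid in pids if pid not in matches.values()]
        if free_g and free_p:
            A = np.full((len(free_g), len(free_p)), -1.0)
            for i, gid in enumerate(free_g):
                for j, pid in enumerate(free_p):
                    aff = _pair_affinity(p[pid], g[gid], iou_match_thr, dist_thr)
                    if aff is not None:
                        A[i, j] = aff
            rows, cols = linear_sum_assignment(-A)
            for i, j in zip(rows, cols):
                if A[i, j] >= 0:
                    matches[free_g[i]] = free_p[j]

        for gid, pid in matches.items():
            if gid in last_match and last_match[gid] != pid:
                ids += 1
            last_match[gid] = pid
            co[(gid, pid)] = co.get((gid, pid), 0) + 1
        n_match += len(matches)
        fn += len(g) - len(matches)
        fp += len(p) - len(matches)

    mota = 1.0 - (fn + fp + ids) / n_gt if n_gt else float("nan")

    # IDF1: optimal global identity assignment on co-occurrence counts
    gids = sorted(gt_obs)
    pids = sorted(pred_obs)
    idtp = 0
    if gids and pids:
        C = np.zeros((len(gids), len(pids)))
        for (gid, pid), c in co.items():
            C[gids.index(gid), pids.index(pid)] = c
        rows, cols = linear_sum_assignment(-C)
        idtp = int(C[rows, cols].sum())
    total_gt = sum(gt_obs.values())
    total_pred = sum(pred_obs.values())
    idfn = total_gt - idtp
    idfp = total_pred - idtp
    denom = 2 * idtp + idfp + idfn
    idf1 = 2 * idtp / denom if denom else float("nan")

    return TrackingEval(mota=float(mota), idf1=float(idf1), ids=ids,
                        fp=fp, fn=fn, n_gt=n_gt, n_matches=n_match)
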