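"""Downstream quantification: morphometry tables, distribution summaries,
trajectories, origin normalization and migration statistics.

This is the only stage where the pixel size (micrometres per pixel) enters:
perimeters scale by ``s`` and areas by ``s**2``; circularity and aspect
ratio are dimensionless.  Trajectory points are contour area centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .geometry import MorphologyRecord

__all__ = [
    "Trajectory",
    "DistributionSummary",
    "morphology_table",
    "morphology_dataframe",
    "distribution_summary",
    "trajectories_from_tracks",
    "origin_normalize",
    "path_length",
    "cohort_compare",
]


@dataclass
class Trajectory:
    """One cell's centroid path: (x um, y um, t minutes) triples."""

    track_id: int
    points: np.ndarray          # (n, 3): x, y, t

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("trajectory points must be (x, y, t) triples")
        if len(self.points) > 1 and np.any(np.diff(self.points[:, 2]) <= 0):
            raise ValueError("trajectory times must strictly increase")


def morphology_table(instances, pixel_size: float) -> list[MorphologyRecord]:
    """One morphometry record per instance, converted to micrometres."""
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    records = []
    for inst in instances:
        c = inst.contour if hasattr(inst, "contour") else inst
        records.append(MorphologyRecord(
            perimeter=geometry.polygon_perimeter(c) * pixel_size,
            area=geometry.polygon_area(c) * pixel_size ** 2,
            circularity=geometry.circularity(c),
            aspect_ratio=geometry.aspect_ratio(c),
        ))
    return records


def morphology_dataframe(instances, pixel_size: float) -> pd.DataFrame:
    recs = morphology_table(instances, pixel_size)
    return pd.DataFrame([vars(r) for r in recs])


@dataclass
class DistributionSummary:
    mean: float
    sd: float
    mode_bin: float                  # centre of the most occupied bin
    counts: np.ndarray
    bin_edges: np.ndarray
    mode_deviates: bool              # histogram mode far from the Gaussian fit

    @property
    def gaussian_fit(self) -> tuple[float, float]:
        """Moment-matched Gaussian overlay parameters (mu, sigma)."""
        return self.mean, self.sd


def distribution_summary(values, bins: int = 30) -> DistributionSummary:
    """Histogram plus moment-matched Gaussian fit of one parameter.

    Emits ``mode_deviates`` when the most occupied bin sits further from
    the fitted mean than max(sd/2, one bin width) — a simple unimodality
    red flag for Gaussian overlays on skewed or bimodal data.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("distribution summary of empty input")
    mean, sd = float(v.mean()), float(v.std())
    counts, edges = np.histogram(v, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[int(np.argmax(counts))])
    width = float(edges[1] - edges[0]) if len(edges) > 1 else 0.0
    deviates = abs(mode - mean) > max(sd / 2.0, width)
    return DistributionSummary(mean=mean, sd=sd, mode_bin=mode,
                               counts=counts, bin_edges=edges,
                               mode_deviates=bool(deviates))


def trajectories_from_tracks(tracks, pixel_size: float = 1.0,
                             frame_interval: float = 10.0) -> list[Trajectory]:
    """Centroid trajectories from Track objects or a frame/track_id/x/y table."""
    out = []
    if hasattr(tracks, "columns"):
        xcol = "x_centroid" if "x_centroid" in tracks.columns else "x"
        ycol = "y_centroid" if "y_centroid" in tracks.columns else "y"
        for tid, grp in tracks.groupby("track_id"):
            grp = grp.sort_values("frame")
            pts = np.column_stack([
                grp[xcol].to_numpy() * pixel_size,
                grp[ycol].to_numpy() * pixel_size,
                grp["frame"].to_numpy() * frame_interval,
            ])
            out.append(Trajectory(track_id=int(tid), points=pts))
        return out
    for tr in tracks:
        pts = []
        for f, inst in tr.observations:
            c = geometry.polygon_centroid(inst.contour)
            pts.append((c[0] * pixel_size, c[1] * pixel_size, f * frame_interval))
        out.append(Trajectory(track_id=tr.track_id, points=np.array(pts)))
    return out


def origin_normalize(traj: Trajectory) -> Trajectory:
    """Translate so the first point is the coordinate origin; time untouched."""
    pts = traj.points.copy()
    pts[:, 0] -= traj.points[0, 0]
    pts[:, 1] -= traj.points[0, 1]
    return Trajectory(track_id=traj.track_id, points=pts)


def path_length(traj: Trajectory) -> float:
    """Cumulative Euclidean arc length of the 2D centroid path, micrometres."""
    if len(traj.points) < 2:
        raise ValueError("path length needs at least two points")
    d = np.diff(traj.points[:, :2], axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def cohort_compare(trajectories_a: list[Trajectory],
                   trajectories_b: list[Trajectory]) -> dict:
    """Descriptive comparison of two trajectory cohorts (no hypothesis test).

    Returns per-group path-length summaries and the A/B mean-length ratio.
    Single-member groups are valid; their sd is reported as NaN with an
    ``sd_undefined`` flag.
    """
    if not trajectories_a or not trajectories_b:
        raise ValueError("both cohorts must be non-empty")

    def _summ(trajs):
        lengths = np.array([path_length(t) for t in trajs if len(t.points) >= 2])
        if lengths.size == 0:
            raise ValueError("cohort has no trajectory with >= 2 points")
        return {
            "n": int(lengths.size),
            "mean_length": float(lengths.mean()),
            "sd_length": float(lengths.std(ddof=1)) if lengths.size > 1 else float("nan"),
            "sd_undefined": lengths.size <= 1,
            "lengths": lengths,
        }

    sa, sb = _summ(trajectories_a), _summ(trajectories_b)
    return {
        "group_a": sa,
        "group_b": sb,
        "mean_length_ratio": sa["mean_length"] / sb["mean_length"],
    }
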