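"""Interchange formats, configuration and seed handling.

Formats
-------
* image stacks: multipage TIFF or a directory of per-frame PNGs, read as
  ordered grayscale frames normalised to [0, 1];
* ``instances.json``: ``{"meta": {...}, "instances": [{frame, id, score,
  vertices: [[x, y], ...]}]}`` — polygons are variable length, hence JSON;
* ``tracks.csv``: columns frame, track_id, x_centroid, y_centroid, score,
  instance_index, with ``# key: value`` metadata header lines;
* config: YAML with one section per pipeline stage; unknown keys are
  rejected so typos fail loudly.

Frame indices are 0-based everywhere.  The global seed fans out to
per-module generators through fixed offsets so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import Contour
from .segmenter import CellInstance

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_image_stack",
    "write_instances",
    "read_instances",
    "write_tracks",
    "read_tracks",
    "write_ctc_tracks",
    "derive_seed",
    "config_hash",
]

_SEED_OFFSETS = {
    "simulate": 11, "backbone": 23, "segmenter": 37,
    "tracker": 53, "quantify": 71,
}

_KNOWN_SECTIONS = {
    "seed", "log_level", "pixel_size", "frame_interval",
    "backbone", "segmenter", "tracker", "simulate", "quantify",
}


class SchemaError(ValueError):
    """A file violated the documented interchange schema."""


def derive_seed(global_seed: int, module: str) -> int:
    """Deterministic per-module seed below 2**31."""
    if module not in _SEED_OFFSETS:
        raise KeyError(f"unknown module {module!r}")
    return (int(global_seed) * 1000003 + _SEED_OFFSETS[module]) % (2 ** 31)


@dataclass
class RunConfig:
    """Resolved run configuration; a bare config is valid end to end."""

    seed: int = 0
    log_level: str = "info"
    pixel_size: float = 1.0          # micrometres per pixel
    frame_interval: float = 10.0     # minutes
    backbone: dict = field(default_factory=dict)
    segmenter: dict = field(default_factory=dict)
    tracker: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _meta(cfg: RunConfig | None = None) -> dict:
    m = {"tool": "dpetrack", "version": __version__}
    if cfg is not None:
        m["config_hash"] = config_hash(cfg)
        m["seed"] = cfg.seed
    return m


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def read_image_stack(path) -> list[np.ndarray]:
    """Read a multipage TIFF or a directory of PNG frames.

    Frames are ordered (pages, or lexicographic file names), converted to
    grayscale and normalised to [0, 1] by the dtype range.  Mixed frame
    shapes raise an error.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        for f in files:
            frames.append(iio.imread(f))
    else:
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            frames = [arr]
        else:
            frames = [arr[i] for i in range(arr.shape[0])]

    out = []
    for fr in frames:
        fr = np.asarray(fr)
        if fr.ndim == 3:          # RGB(A) -> luminance
            fr = fr[..., :3].mean(axis=-1)
        if fr.dtype == np.uint8:
            fr = fr.astype(float) / 255.0
        elif fr.dtype == np.uint16:
            fr = fr.astype(float) / 65535.0
        else:
            fr = fr.astype(float)
            if fr.max() > 1.0:
                fr = fr / fr.max()
        out.append(fr)
    shapes = {f.shape for f in out}
    if len(shapes) > 1:
        raise SchemaError(f"mixed frame shapes: {sorted(shapes)}")
    return out


def write_image_stack(path, stack: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack))


# ---------------------------------------------------------------------------
# Instances
# ---------------------------------------------------------------------------

def write_instances(path, instances: list[CellInstance],
                    cfg: RunConfig | None = None) -> None:
    payload = {
        "meta": _meta(cfg),
        "instances": [
            {
                "frame": int(inst.frame),
                "id": None if inst.id is None else int(inst.id),
                "score": float(inst.score),
                "vertices": np.asarray(inst.contour.vertices).tolist(),
            }
            for inst in instances
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_instances(path) -> list[CellInstance]:
    raw = json.loads(Path(path).read_text())
    if "instances" not in raw:
        raise SchemaError("missing 'instances' key")
    out = []
    for k, rec in enumerate(raw["instances"]):
        try:
            out.append(CellInstance(
                frame=int(rec["frame"]),
                contour=Contour.from_vertices(rec["vertices"]),
                score=float(rec["score"]),
                id=rec.get("id"),
            ))
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"instance record {k}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

_TRACK_COLS = ["frame", "track_id", "x_centroid", "y_centroid",
               "score", "instance_index"]


def write_tracks(path, tracks, cfg: RunConfig | None = None) -> None:
    """Write Track objects (or a prebuilt dataframe) to tracks.csv."""
    from . import geometry

    if hasattr(tracks, "columns"):
        df = tracks[_TRACK_COLS]
    else:
        rows = []
        for tr in tracks:
            for k, (f, inst) in enumerate(tr.observations):
                c = geometry.polygon_centroid(inst.contour)
                rows.append((f, tr.track_id, float(c[0]), float(c[1]),
                             float(inst.score), k))
        df = pd.DataFrame(rows, columns=_TRACK_COLS).sort_values(
            ["frame", "track_id"]).reset_index(drop=True)
    with open(path, "w") as fh:
        for k, v in _meta(cfg).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"frame", "track_id"} - set(df.columns)
    if not missing and not ({"x_centroid", "y_centroid"} <= set(df.columns)
                            or {"x", "y"} <= set(df.columns)):
        missing = {"x_centroid", "y_centroid"}
    if missing:
        raise SchemaError(f"tracks.csv missing columns: {sorted(missing)}")
    for tid, grp in df.groupby("track_id"):
        fr = grp["frame"].to_numpy()
        if np.any(np.diff(fr) <= 0) if len(fr) > 1 else False:
            raise SchemaError(f"non-monotone frames for track_id {tid}")
    return df


def write_ctc_tracks(path, tracks) -> None:
    """Cell-Tracking-Challenge-style res_track.txt: id, start, end, parent."""
    with open(path, "w") as fh:
        for tr in tracks:
            frames = [f for f, _ in tr.observations]
            fh.write(f"{tr.track_id} {min(frames)} {max(frames)} 0\n")
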