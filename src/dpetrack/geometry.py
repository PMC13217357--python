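"""Contour primitives, Freeman chain codes, morphometry and pairwise similarities.

All geometry works in pixel units with the image coordinate convention:
origin at the top-left corner, x increasing rightward, y increasing
downward, sub-pixel float coordinates.  Contours are implicitly closed
(the last vertex connects back to the first) and are stored with positive
signed shoelace area, which this module calls counter-clockwise.

Physical units (micrometres) enter only in :mod:`dpetrack.quantify` via the
pixel-size scalar; everything here is unit-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely.geometry as sgeom
from shapely import make_valid
from shapely.ops import unary_union

__all__ = [
    "Contour",
    "ChainCode",
    "MorphologyRecord",
    "InvalidContourError",
    "polygon_area",
    "signed_area",
    "polygon_perimeter",
    "polygon_centroid",
    "circularity",
    "aspect_ratio",
    "min_rect_sides",
    "polygon_iou",
    "contour_similarity",
    "shape_similarity",
    "chain_encode",
    "chain_decode",
    "trace_boundary",
    "resample_contour",
    "smooth_contour",
    "remove_noise",
    "rasterize_contour",
    "is_simple",
]


class InvalidContourError(ValueError):
    """Raised when a polygon violates the contour preconditions."""


@dataclass(frozen=True)
class Contour:
    """Closed polygon delineating one cell instance.

    Parameters
    ----------
    vertices
        ``(N, 2)`` array of ``(x, y)`` sub-pixel coordinates, ``N >= 3``.
        Orientation is normalised to positive shoelace area on
        construction unless ``orient=False`` is passed via
        :meth:`from_vertices`.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidContourError(
                f"contour needs an (N>=3, 2) vertex array, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidContourError("contour coordinates must be finite")
        object.__setattr__(self, "vertices", v)

    @classmethod
    def from_vertices(cls, vertices, orient: bool = True) -> "Contour":
        c = cls(np.asarray(vertices, dtype=float))
        if orient and signed_area(c) < 0:
            c = cls(c.vertices[::-1].copy())
        return c

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices[:, 0], self.vertices[:, 1]

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + np.array([dx, dy]))

    def to_shapely(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.vertices)


@dataclass(frozen=True)
class ChainCode:
    """Freeman 8-direction encoding of a closed pixel boundary path."""

    start: tuple[int, int]
    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c not in range(8) for c in self.codes):
            raise ValueError("chain codes must lie in 0..7")


@dataclass(frozen=True)
class MorphologyRecord:
    """Per-cell morphometry in physical units (micrometres)."""

    perimeter: float
    area: float
    circularity: float
    aspect_ratio: float


# Freeman code k -> (dx, dy) in image coordinates (y down); code 0 points
# east and codes advance counter-clockwise on screen (2 = up = -y).
_FREEMAN_STEPS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1),
)
_STEP_TO_CODE = {s: k for k, s in enumerate(_FREEMAN_STEPS)}


def _verts(c: Contour | np.ndarray) -> np.ndarray:
    if isinstance(c, Contour):
        return c.vertices
    v = np.asarray(c, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise InvalidContourError(f"need an (N>=3, 2) vertex array, got {v.shape}")
    return v


def signed_area(c: Contour | np.ndarray) -> float:
    """Signed shoelace area; positive for this module's CCW convention."""
    v = _verts(c)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(c: Contour | np.ndarray) -> float:
    """Unsigned shoelace area in px²."""
    return abs(signed_area(c))


def polygon_perimeter(c: Contour | np.ndarray) -> float:
    """Sum of consecutive-vertex Euclidean distances, closing edge included."""
    v = _verts(c)
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_centroid(c: Contour | np.ndarray) -> np.ndarray:
    """Area centroid of the closed polygon (falls back to vertex mean when
    the polygon is degenerate)."""
    v = _verts(c)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-12:
        return v.mean(axis=0)
    cx = float(((x + xn) * cross).sum() / (6.0 * a))
    cy = float(((y + yn) * cross).sum() / (6.0 * a))
    return np.array([cx, cy])


def circularity(c: Contour | np.ndarray) -> float:
    """Isoperimetric ratio 4·pi·A / P²; equals 1 for a disk.

    Discretisation can push the value marginally above 1 for very fine
    polygons, hence the documented ``<= 1 + eps`` contract.
    """
    p = polygon_perimeter(c)
    if p <= 0:
        raise InvalidContourError("zero-perimeter polygon has no circularity")
    return 4.0 * np.pi * polygon_area(c) / (p * p)


def min_rect_sides(c: Contour | np.ndarray) -> tuple[float, float]:
    """(major, minor) side lengths of the minimum-area rotated bounding box."""
    poly = sgeom.Polygon(_verts(c))
    rect = poly.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate (collinear) input
        raise InvalidContourError("degenerate polygon has no rotated bounding box")
    coords = np.asarray(rect.exterior.coords)[:4]
    e1 = float(np.linalg.norm(coords[1] - coords[0]))
    e2 = float(np.linalg.norm(coords[2] - coords[1]))
    return (max(e1, e2), min(e1, e2))


def aspect_ratio(c: Contour | np.ndarray) -> float:
    """Minor/major side of the minimum-area rotated rectangle, in (0, 1]."""
    major, minor = min_rect_sides(c)
    if major <= 0 or minor <= 0:
        raise InvalidContourError("zero-width polygon has no aspect ratio")
    return minor / major


def _clean_poly(v: np.ndarray) -> sgeom.base.BaseGeometry:
    p = sgeom.Polygon(v)
    if not p.is_valid:
        p = make_valid(p)
    return p


def polygon_iou(a: Contour | np.ndarray, b: Contour | np.ndarray) -> float:
    """Exact polygon-clipping intersection over union, in [0, 1]."""
    pa, pb = _clean_poly(_verts(a)), _clean_poly(_verts(b))
    inter = pa.intersection(pb).area
    union = unary_union([pa, pb]).area
    if union <= 0:
        return 0.0
    return float(np.clip(inter / union, 0.0, 1.0))


def contour_similarity(a: Contour | np.ndarray, b: Contour | np.ndarray) -> float:
    """Bounded translation-invariant shape agreement in [0, 1].

    Both contours are centred on their area centroids; the score is
    ``1 - d_H / (d_H + D)`` where ``d_H`` is the symmetric Hausdorff
    distance between the aligned boundaries (densified, so invariant to
    the vertex starting index) and ``D`` is the geometric mean of the two
    major-axis lengths.  Congruent translated contours score 1; the score
    decays toward 0 as shapes diverge on the scale of the cells
    themselves, and drops below 0.5 once the discrepancy exceeds the
    joint size scale (e.g. a compact cell vs a long sliver).
    """
    va, vb = _verts(a), _verts(b)
    la = sgeom.LineString(np.vstack([va, va[:1]]) - polygon_centroid(va))
    lb = sgeom.LineString(np.vstack([vb, vb[:1]]) - polygon_centroid(vb))
    import shapely

    d_h = shapely.hausdorff_distance(la, lb, densify=0.05)
    scale = float(np.sqrt(min_rect_sides(va)[0] * min_rect_sides(vb)[0]))
    if scale <= 0:
        return 0.0
    return float(1.0 - d_h / (d_h + scale))


def shape_similarity(a, b) -> float:
    """Sum of three bounded shape-agreement terms, in [0, 3].

    Terms: area ratio ``min/max``, aspect-ratio agreement ``1 - |r_a - r_b|``
    and :func:`contour_similarity`.  Identical (possibly translated) shapes
    score exactly 3.  Accepts contours or objects with a ``contour``
    attribute (cell instances).
    """
    ca = a.contour if hasattr(a, "contour") else a
    cb = b.contour if hasattr(b, "contour") else b
    a1, a2 = polygon_area(ca), polygon_area(cb)
    if max(a1, a2) <= 0:
        return 0.0
    t_area = min(a1, a2) / max(a1, a2)
    t_ar = 1.0 - abs(aspect_ratio(ca) - aspect_ratio(cb))
    return float(t_area + t_ar + contour_similarity(ca, cb))


# ---------------------------------------------------------------------------
# Freeman chain codes
# ---------------------------------------------------------------------------

def chain_encode(path: Sequence[tuple[int, int]] | np.ndarray) -> ChainCode:
    """Encode a closed 8-connected pixel path as Freeman chain codes.

    The path may or may not repeat its first pixel at the end; a
    single-pixel object encodes as an empty code sequence.
    """
    p = np.asarray(path, dtype=int)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) == 0:
        raise ValueError("path must be a non-empty (N, 2) integer array")
    if len(p) > 1 and np.array_equal(p[0], p[-1]):
        p = p[:-1]
    if len(p) == 1:
        return ChainCode(start=(int(p[0, 0]), int(p[0, 1])), codes=())
    codes = []
    for k in range(len(p)):
        dx, dy = p[(k + 1) % len(p)] - p[k]
        step = (int(dx), int(dy))
        if step not in _STEP_TO_CODE:
            raise ValueError(
                f"path not 8-connected at index {k}: step {step}"
            )
        codes.append(_STEP_TO_CODE[step])
    return ChainCode(start=(int(p[0, 0]), int(p[0, 1])), codes=tuple(codes))


def chain_decode(cc: ChainCode) -> np.ndarray:
    """Decode a chain code back to its closed pixel path (start excluded at
    the end; ``decode(encode(p)) == p``)."""
    pts = [cc.start]
    for code in cc.codes:
        dx, dy = _FREEMAN_STEPS[code]
        x, y = pts[-1]
        pts.append((x + dx, y + dy))
    arr = np.asarray(pts, dtype=int)
    if len(cc.codes) and not np.array_equal(arr[0], arr[-1]):
        raise ValueError("chain code does not close onto its start pixel")
    if len(cc.codes):
        arr = arr[:-1]
    return arr


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbour trace of the outer boundary of a binary mask.

    Returns the ordered (x, y) pixel path of the largest foreground
    component's outer boundary, 8-connected and closed, suitable for
    :func:`chain_encode`.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask has no boundary")
    # start: topmost of leftmost foreground pixels -> backtrack points west
    order = np.lexsort((ys, xs))
    sx, sy = int(xs[order[0]]), int(ys[order[0]])
    if len(xs) == 1:
        return np.array([[sx, sy]], dtype=int)

    def inside(x: int, y: int) -> bool:
        return 0 <= y < mask.shape[0] and 0 <= x < mask.shape[1] and mask[y, x]

    # Moore neighbourhood in clockwise screen order starting west
    nbrs = ((-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1))
    path = [(sx, sy)]
    backtrack = 0  # index into nbrs of the pixel we entered from (west)
    cx, cy = sx, sy
    for _ in range(8 * mask.size):
        found = False
        for k in range(1, 9):
            idx = (backtrack + k) % 8
            nx, ny = cx + nbrs[idx][0], cy + nbrs[idx][1]
            if inside(nx, ny):
                backtrack = (idx + 4) % 8  # direction pointing back at (cx,cy)
                cx, cy = nx, ny
                found = True
                break
        if not found:  # isolated pixel reached via spur
            break
        if (cx, cy) == (sx, sy):
            return np.asarray(path, dtype=int)
        path.append((cx, cy))
    return np.asarray(path, dtype=int)


# ---------------------------------------------------------------------------
# Resampling / smoothing / filtering
# ---------------------------------------------------------------------------

def _resample_once(v: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([v, v[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise InvalidContourError("zero-perimeter contour cannot be resampled")
    t = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([np.interp(t, s, closed[:, 0]),
                            np.interp(t, s, closed[:, 1])])


def resample_contour(c: Contour | np.ndarray, n: int) -> Contour:
    """Resample to ``n`` vertices equally spaced by arc length.

    Vertex 0 of the output stays at vertex 0 of the input; the spacing
    pass is iterated to its fixed point (all chords equal), which makes
    the operation idempotent at fixed ``n``.
    """
    if n < 3:
        raise InvalidContourError("resampling needs n >= 3")
    v = _resample_once(_verts(c), n)
    for _ in range(40):
        nxt = _resample_once(v, n)
        move = np.abs(nxt - v).max()
        v = nxt
        if move < 1e-10:
            break
    return Contour(v)


def smooth_contour(c: Contour | np.ndarray, window: int) -> Contour:
    """Circular moving-average smoothing of the vertex sequence."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    v = _verts(c)
    if window == 1:
        return Contour(v.copy())
    k = window // 2
    ext = np.vstack([v[-k:], v, v[:k]])
    kernel = np.ones(window) / window
    x = np.convolve(ext[:, 0], kernel, mode="valid")
    y = np.convolve(ext[:, 1], kernel, mode="valid")
    return Contour(np.column_stack([x, y]))


def remove_noise(instances: Iterable, min_area: float) -> list:
    """Drop instances whose polygon area falls below ``min_area`` px²."""
    kept = []
    for inst in instances:
        c = inst.contour if hasattr(inst, "contour") else inst
        if polygon_area(c) >= min_area:
            kept.append(inst)
    return kept


def rasterize_contour(c: Contour | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask with centre-of-pixel ownership: pixel (i, j) is set when
    its centre (x=j, y=i) lies inside the polygon."""
    from skimage.draw import polygon as _sk_polygon

    v = _verts(c)
    rr, cc = _sk_polygon(v[:, 1], v[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def is_simple(c: Contour | np.ndarray) -> bool:
    """True when the closed polygon does not self-intersect."""
    return bool(sgeom.Polygon(_verts(c)).is_valid)
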