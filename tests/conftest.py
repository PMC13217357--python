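import numpy as np
import pytest

from dpetrack import simulate as dsim
from dpetrack.geometry import Contour


@pytest.fixture(scope="session")
def unit_square() -> Contour:
    return Contour.from_vertices([(0, 0), (1, 0), (1, 1), (0, 1)])


def regular_ngon(n: int, radius: float = 1.0, center=(0.0, 0.0)) -> Contour:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour.from_vertices(
        np.column_stack([center[0] + radius * np.cos(theta),
                         center[1] + radius * np.sin(theta)]))


def random_convex_polygon(rng: np.random.Generator, n_points: int = 12,
                          scale: float = 10.0, center=(0.0, 0.0)) -> Contour:
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n_points, 2)) * scale + np.asarray(center)
    hull = ConvexHull(pts)
    return Contour.from_vertices(pts[hull.vertices])


@pytest.fixture(scope="session")
def star_scene():
    """Clean rendered 5-spike star with known tip coordinates."""
    cfg = dsim.SceneConfig(width=96, height=96, n_cells=1, duration=0,
                           noise_sd=0.0, seed=1,
                           n_protrusions=(5, 5), protrusion_length=(8, 10))
    rng = np.random.default_rng(2)
    star, tips = dsim.generate_cell_shape(cfg, rng, n_protrusions=5)
    center = np.array([48.0, 48.0])
    contour = Contour.from_vertices(star.vertices + center)
    tips = tips + center
    img = dsim._render_frame(cfg, [contour.vertices],
                             np.random.default_rng(0)).astype(float) / 255.0
    return {"cfg": cfg, "contour": contour, "tips": tips, "image": img,
            "center": center}


@pytest.fixture(scope="session")
def small_sequence():
    """Short noisy multi-cell sequence with ground truth."""
    cfg = dsim.SceneConfig(width=160, height=160, n_cells=6, duration=70,
                           frame_interval=10.0, seed=3)
    stack, gt = dsim.simulate_sequence(cfg)
    return {"cfg": cfg, "stack": stack, "gt": gt}


def make_training_frames(n: int, seed0: int, n_cells: int = 5, size: int = 128):
    """Independent single-frame scenes for segmenter training/evaluation."""
    out = []
    for k in range(n):
        cfg = dsim.SceneConfig(width=size, height=size, n_cells=n_cells,
                               duration=0, noise_sd=0.02, seed=seed0 + k)
        stack, gt = dsim.simulate_sequence(cfg)
        out.append((stack[0].astype(float) / 255.0,
                    list(gt.polygons[0].values())))
    return out
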