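import numpy as np
import pytest

from granmorph import pipeline as pl


@pytest.fixture(scope="session")
def disk100():
    """Rasterised disk, radius 100 px (1.0 mm at 0.01 mm/px)."""
    return pl.disk_mask(100)


@pytest.fixture(scope="session")
def square100():
    """Axis-aligned filled square, side 100 px (1.0 mm at 0.01 mm/px)."""
    return pl.square_mask(100)


@pytest.fixture(scope="session")
def cross_3x1():
    """Cross of two 3 mm x 1 mm rectangles at 0.01 mm/px (A=5, CH_A=7 mm^2)."""
    return pl.cross_mask(300, 100)


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's close approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def brute_force_feret(points: np.ndarray, step_deg: float = 0.1):
    """(max, min) directional width by dense angle sweep — independent oracle."""
    pts = np.asarray(points, dtype=float)
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = pts @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())


def random_convex_polygon(rng: np.random.Generator, n_points: int = 30) -> np.ndarray:
    """Convex polygon as the hull of random points in a random-aspect box."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n_points, 2)) * rng.uniform(0.5, 3.0, size=2)
    return pts[ConvexHull(pts).vertices]
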