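"""Shared fixtures and the rasterized-integration oracle.

The polygon engine uses exact per-edge closed forms; these tests check it
against (a) analytic shapes and (b) a brute-force grid integration that
knows nothing about Green's theorem.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
import shapely

from sterome.geometry import CrossSection, PolygonOutline, TissueRegion


def circle_vertices(r: float, n: int = 512, cx: float = 0.0, cy: float = 0.0) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def grid_moments(mask_fn, bounds, n=2000):
    """Brute-force second moments about the area centroid on an n x n grid.

    ``mask_fn(X, Y) -> bool array`` defines region membership; ``bounds`` is
    (x0, x1, y0, y1).  Returns (area, (cx, cy), ixx, iyy, ixy).
    """
    x0, x1, y0, y1 = bounds
    xs = np.linspace(x0, x1, n, endpoint=False) + (x1 - x0) / (2 * n)
    ys = np.linspace(y0, y1, n, endpoint=False) + (y1 - y0) / (2 * n)
    X, Y = np.meshgrid(xs, ys)
    dA = (x1 - x0) * (y1 - y0) / (n * n)
    m = mask_fn(X, Y)
    area = m.sum() * dA
    cx = (X * m).sum() * dA / area
    cy = (Y * m).sum() * dA / area
    ixx = (((Y - cy) ** 2) * m).sum() * dA
    iyy = (((X - cx) ** 2) * m).sum() * dA
    ixy = ((X - cx) * (Y - cy) * m).sum() * dA
    return area, (cx, cy), ixx, iyy, ixy


def shapely_mask(geom):
    """Membership function for :func:`grid_moments` from a shapely geometry."""

    def mask(X, Y):
        return shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(X.shape)

    return mask


@pytest.fixture
def annulus_section() -> CrossSection:
    """The concentric reference fixture: sclerenchyma annulus 0.8-1.0 mm
    radius over a parenchyma disc, 512-gon boundaries."""
    sterome = TissueRegion(
        "sclerenchyma",
        PolygonOutline(circle_vertices(1.0)),
        holes=[PolygonOutline(circle_vertices(0.8))],
    )
    core = TissueRegion("parenchyma", PolygonOutline(circle_vertices(0.8)))
    return CrossSection([sterome, core])


def random_star_polygon(rng: np.random.Generator, n: int = 12) -> np.ndarray:
    """A random simple (star-shaped) polygon around a random center.

    Vertex angles are jittered regular spacings, which keeps every angular
    gap below pi and so guarantees a simple boundary.
    """
    base = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    angles = base + rng.uniform(-0.3, 0.3, n) * (2.0 * math.pi / n)
    radii = rng.uniform(0.5, 2.0, n)
    cx, cy = rng.uniform(-3.0, 3.0, 2)
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
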