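"""Exact section properties of digitized petiole tissue outlines.

A petiole cross-section is represented as a set of labeled tissue regions
(sclerenchyma, parenchyma, xylem, phloem), each a simple polygon with optional
holes, in the natural dorso-ventral orientation: the y axis is vertical
(dorso-ventral), the x axis horizontal (lateral).  All lengths are millimetres,
areas mm^2 and second moments of area mm^4.

Area, centroid and the second moments of area are evaluated with the
closed-form per-edge expressions obtained from Green's theorem on the polygon
boundary, so results are exact for the polygon (no rasterization).  Per-tissue
moments are referred to axes through the *whole-section* area centroid — the
neutral line of bending — so that moments are additive across tissues:

    I_total = sum_i I_i

``i_x`` denotes the moment about the horizontal axis (resisting bending in the
vertical, dorso-ventral plane) and ``i_y`` the moment about the vertical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "TISSUES",
    "GeometryError",
    "PlaneMoments",
    "PolygonOutline",
    "TissueRegion",
    "CrossSection",
    "SectionMoments",
    "polygon_properties",
    "section_centroid",
    "tissue_moments",
]

#: Tissue labels recognised in a cross-section, ordered from stiffest to softest.
TISSUES = ("sclerenchyma", "xylem", "phloem", "parenchyma")

#: Tolerated overlap between regions of different tissues, as a fraction of
#: total section area.  Hand-drawn outlines abut imperfectly.
OVERLAP_TOLERANCE = 1e-6

_DEGENERATE_AREA = 1e-300


class GeometryError(ValueError):
    """An outline or section violates its geometric invariants."""


@dataclass(frozen=True)
class PlaneMoments:
    """Area, centroid and second moments of a plane region about given axes.

    ``ixx`` is the moment about the horizontal (x-parallel) axis through the
    reference point, ``iyy`` about the vertical axis, ``ixy`` the product
    moment.
    """

    area: float
    centroid: tuple[float, float]
    ixx: float
    iyy: float
    ixy: float

    def __add__(self, other: "PlaneMoments") -> "PlaneMoments":
        a = self.area + other.area
        cx = (self.area * self.centroid[0] + other.area * other.centroid[0]) / a
        cy = (self.area * self.centroid[1] + other.area * other.centroid[1]) / a
        return PlaneMoments(
            a, (cx, cy), self.ixx + other.ixx, self.iyy + other.iyy, self.ixy + other.ixy
        )

    def __sub__(self, other: "PlaneMoments") -> "PlaneMoments":
        a = self.area - other.area
        if abs(a) < _DEGENERATE_AREA:
            raise GeometryError("subtracting regions of equal area leaves no material")
        cx = (self.area * self.centroid[0] - other.area * other.centroid[0]) / a
        cy = (self.area * self.centroid[1] - other.area * other.centroid[1]) / a
        return PlaneMoments(
            a, (cx, cy), self.ixx - other.ixx, self.iyy - other.iyy, self.ixy - other.ixy
        )


def _edge_terms(v: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Green's-theorem edge sums for a closed polygon given as (n, 2) vertices.

    Returns signed ``(area, Sx, Sy, Ixx, Iyy, Ixy)`` about the coordinate
    origin; positive for counter-clockwise orientation.
    """
    x = v[:, 0]
    y = v[:, 1]
    x2 = np.roll(x, -1)
    y2 = np.roll(y, -1)
    c = x * y2 - x2 * y
    area = 0.5 * float(np.sum(c))
    sx = float(np.sum((x + x2) * c)) / 6.0  # area * centroid_x
    sy = float(np.sum((y + y2) * c)) / 6.0
    ixx = float(np.sum((y * y + y * y2 + y2 * y2) * c)) / 12.0
    iyy = float(np.sum((x * x + x * x2 + x2 * x2) * c)) / 12.0
    ixy = float(np.sum((x * y2 + 2.0 * x * y + 2.0 * x2 * y2 + x2 * y) * c)) / 24.0
    return area, sx, sy, ixx, iyy, ixy


class PolygonOutline:
    """A simple closed polygon boundary (implicitly closed, CCW-normalized).

    Parameters
    ----------
    vertices
        Sequence of (x, y) points in mm.  The last vertex connects back to the
        first; a repeated closing vertex is tolerated and dropped.  Either
        winding order may be supplied; storage is counter-clockwise.
    label
        Optional name used in diagnostics.
    """

    __slots__ = ("vertices", "label")

    def __init__(self, vertices: Sequence[Sequence[float]], label: str | None = None):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError(f"outline {label or ''!s}: vertices must be (n, 2) points")
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise GeometryError(
                f"outline {label or '<unnamed>'}: needs at least 3 vertices, got {len(v)}"
            )
        if not np.all(np.isfinite(v)):
            raise GeometryError(f"outline {label or '<unnamed>'}: non-finite coordinates")
        signed = _edge_terms(v)[0]
        if abs(signed) < 1e-15 * max(1.0, float(np.abs(v).max()) ** 2):
            raise GeometryError(f"outline {label or '<unnamed>'}: zero signed area (degenerate)")
        if signed < 0:
            v = v[::-1].copy()
        poly = _ShapelyPolygon(v)
        if not poly.is_valid:
            raise GeometryError(
                f"outline {label or '<unnamed>'}: self-intersecting or otherwise invalid boundary"
            )
        self.vertices = v
        self.vertices.setflags(write=False)
        self.label = label

    def __len__(self) -> int:
        return len(self.vertices)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PolygonOutline(n={len(self)}, label={self.label!r})"

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "PolygonOutline":
        return PolygonOutline(self.vertices + np.array([dx, dy]), label=self.label)

    def rotated90(self) -> "PolygonOutline":
        """Rotate 90 degrees counter-clockwise about the origin."""
        v = self.vertices
        return PolygonOutline(np.column_stack([-v[:, 1], v[:, 0]]), label=self.label)


def polygon_properties(
    outline: PolygonOutline, reference: Sequence[float] = (0.0, 0.0)
) -> PlaneMoments:
    """Area, centroid and second moments of ``outline`` about axes through
    ``reference``.

    Moments are about x- and y-parallel axes through the reference point:
    ``ixx`` (about the horizontal axis) governs bending in the vertical plane.
    The centroid is reported in the original coordinate frame.
    """
    ref = np.asarray(reference, dtype=float)
    v = outline.vertices - ref
    area, sx, sy, ixx, iyy, ixy = _edge_terms(v)
    cx, cy = sx / area, sy / area
    return PlaneMoments(
        area=area,
        centroid=(cx + ref[0], cy + ref[1]),
        ixx=ixx,
        iyy=iyy,
        ixy=ixy,
    )


class TissueRegion:
    """One tissue area: an outer boundary minus any holes.

    Holes must lie inside the outer boundary and be pairwise disjoint; the net
    area (outer minus holes) must be positive.
    """

    __slots__ = ("tissue", "outer", "holes")

    def __init__(
        self,
        tissue: str,
        outer: PolygonOutline,
        holes: Iterable[PolygonOutline] = (),
    ):
        if tissue not in TISSUES:
            raise GeometryError(
                f"unknown tissue {tissue!r}; expected one of {', '.join(TISSUES)}"
            )
        holes = tuple(holes)
        outer_poly = outer.shapely
        for i, h in enumerate(holes):
            hp = h.shapely
            if not hp.within(outer_poly):
                raise GeometryError(
                    f"{tissue} region: hole {h.label or i} is not strictly inside the outer boundary"
                )
            for j in range(i + 1, len(holes)):
                other = holes[j].shapely
                if hp.intersection(other).area > 0:
                    raise GeometryError(
                        f"{tissue} region: holes {h.label or i} and {holes[j].label or j} overlap"
                    )
        self.tissue = tissue
        self.outer = outer
        self.holes = holes
        if self.net_area <= 0:
            raise GeometryError(f"{tissue} region: net area (outer minus holes) must be positive")

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(
            self.outer.vertices, [h.vertices for h in self.holes]
        )

    @property
    def net_area(self) -> float:
        a = polygon_properties(self.outer).area
        return a - sum(polygon_properties(h).area for h in self.holes)

    def moments_about(self, reference: Sequence[float]) -> PlaneMoments:
        """Net moments of the region (holes subtracted) about ``reference``."""
        m = polygon_properties(self.outer, reference)
        for h in self.holes:
            m = m - polygon_properties(h, reference)
        return m


class CrossSection:
    """A full petiole cross-section: labeled tissue regions in one frame.

    Multiple regions of the same tissue are permitted (e.g. several vascular
    bundles); regions of different tissues must not overlap beyond
    ``OVERLAP_TOLERANCE`` of the section area.
    """

    __slots__ = ("regions", "orientation", "units")

    def __init__(
        self,
        regions: Sequence[TissueRegion],
        orientation: Mapping[str, str] | None = None,
        units: str = "mm",
    ):
        regions = tuple(regions)
        if not regions:
            raise GeometryError("a cross-section needs at least one tissue region")
        total = sum(r.net_area for r in regions)
        for i, a in enumerate(regions):
            pa = a.shapely
            for b in regions[i + 1 :]:
                inter = pa.intersection(b.shapely).area
                if inter > OVERLAP_TOLERANCE * total:
                    raise GeometryError(
                        f"regions of tissues {a.tissue!r} and {b.tissue!r} overlap "
                        f"by {inter:.3g} mm^2 (> {OVERLAP_TOLERANCE:g} of section area)"
                    )
        self.regions = regions
        self.orientation = dict(orientation or {"y": "dorsoventral", "x": "lateral"})
        self.units = units

    def tissues(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.regions:
            if r.tissue not in seen:
                seen.append(r.tissue)
        return tuple(seen)

    def translated(self, dx: float, dy: float) -> "CrossSection":
        return CrossSection(
            [
                TissueRegion(
                    r.tissue,
                    r.outer.translated(dx, dy),
                    [h.translated(dx, dy) for h in r.holes],
                )
                for r in self.regions
            ],
            orientation=self.orientation,
            units=self.units,
        )

    def rotated90(self) -> "CrossSection":
        return CrossSection(
            [
                TissueRegion(
                    r.tissue, r.outer.rotated90(), [h.rotated90() for h in r.holes]
                )
                for r in self.regions
            ],
            orientation=self.orientation,
            units=self.units,
        )


@dataclass(frozen=True)
class SectionMoments:
    """Per-tissue and total section properties about the centroidal axes.

    All per-tissue entries are referred to axes through the whole-section area
    centroid, so they sum to the totals.  ``i_x`` is the moment about the
    horizontal axis (bending in the vertical plane), ``i_y`` about the
    vertical axis; ``i_xy`` is the product moment (reported, but unused by the
    rigidity equations downstream).
    """

    centroid: tuple[float, float]
    area: dict[str, float]
    i_x: dict[str, float]
    i_y: dict[str, float]
    i_xy: dict[str, float]

    @property
    def total_area(self) -> float:
        return sum(self.area.values())

    @property
    def total_i_x(self) -> float:
        return sum(self.i_x.values())

    @property
    def total_i_y(self) -> float:
        return sum(self.i_y.values())

    @property
    def total_i_xy(self) -> float:
        return sum(self.i_xy.values())

    def tissues(self) -> tuple[str, ...]:
        return tuple(self.area)


def section_centroid(section: CrossSection) -> tuple[float, float]:
    """Area-weighted centroid of the union of all tissue net areas (mm).

    Holes subtract; the result does not depend on the order regions are
    listed.  This is the "center of mass" through which the neutral lines of
    bending are taken.
    """
    a_total = 0.0
    sx = 0.0
    sy = 0.0
    for region in section.regions:
        m = region.moments_about((0.0, 0.0))
        a_total += m.area
        sx += m.area * m.centroid[0]
        sy += m.area * m.centroid[1]
    if a_total <= 0:
        raise GeometryError("section has non-positive total area")
    return (sx / a_total, sy / a_total)


def tissue_moments(section: CrossSection) -> SectionMoments:
    """Per-tissue second moments of area about the whole-section centroid.

    Each region's moments are evaluated directly about axes through the
    section centroid (equivalent to a parallel-axis transfer from the region's
    own centroid); holes subtract; multiple regions of one tissue accumulate.
    """
    c = section_centroid(section)
    area: dict[str, float] = {}
    i_x: dict[str, float] = {}
    i_y: dict[str, float] = {}
    i_xy: dict[str, float] = {}
    for region in section.regions:
        m = region.moments_about(c)
        area[region.tissue] = area.get(region.tissue, 0.0) + m.area
        i_x[region.tissue] = i_x.get(region.tissue, 0.0) + m.ixx
        i_y[region.tissue] = i_y.get(region.tissue, 0.0) + m.iyy
        i_xy[region.tissue] = i_xy.get(region.tissue, 0.0) + m.ixy
    return SectionMoments(centroid=c, area=area, i_x=i_x, i_y=i_y, i_xy=i_xy)
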