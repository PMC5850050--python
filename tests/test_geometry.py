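"""Polygon moment engine: analytic shapes, oracle equivalence, invariants."""

import math

import numpy as np
import pytest

from sterome.geometry import (
    CrossSection,
    GeometryError,
    PolygonOutline,
    TissueRegion,
    polygon_properties,
    section_centroid,
    tissue_moments,
)

from conftest import circle_vertices, grid_moments, random_star_polygon


class TestPolygonProperties:
    def test_unit_square_about_centroid(self):
        sq = PolygonOutline([(0, 0), (1, 0), (1, 1), (0, 1)])
        m = polygon_properties(sq, reference=(0.5, 0.5))
        assert m.area == pytest.approx(1.0)
        assert m.centroid == pytest.approx((0.5, 0.5))
        assert m.ixx == pytest.approx(1 / 12)
        assert m.iyy == pytest.approx(1 / 12)
        assert m.ixy == pytest.approx(0.0, abs=1e-15)

    def test_rectangle_2_by_1(self):
        rect = PolygonOutline([(0, 0), (2, 0), (2, 1), (0, 1)])
        m = polygon_properties(rect, reference=(1.0, 0.5))
        assert m.ixx == pytest.approx(2 * 1**3 / 12)  # b h^3 / 12 about horizontal
        assert m.iyy == pytest.approx(1 * 2**3 / 12)

    def test_narrow_petiole_circle(self):
        # 512-gon inscribed in a 0.45 mm diameter circle: the smallest stipe
        m = polygon_properties(PolygonOutline(circle_vertices(0.225)), (0, 0))
        analytic = math.pi * 0.45**4 / 64
        assert m.ixx == pytest.approx(analytic, rel=1e-3)
        assert round(m.ixx, 3) == 0.002

    def test_ellipse_against_grid_oracle(self):
        a, b = 2.0, 1.0
        theta = np.linspace(0, 2 * math.pi, 512, endpoint=False)
        ell = PolygonOutline(np.column_stack([a * np.cos(theta), b * np.sin(theta)]))
        m = polygon_properties(ell, (0, 0))
        assert m.ixx == pytest.approx(math.pi * a * b**3 / 4, rel=1e-3)
        assert m.iyy == pytest.approx(math.pi * b * a**3 / 4, rel=1e-3)
        _, _, ixx, iyy, _ = grid_moments(
            lambda X, Y: (X / a) ** 2 + (Y / b) ** 2 <= 1.0, (-2.2, 2.2, -1.2, 1.2)
        )
        assert m.ixx == pytest.approx(ixx, rel=2e-3)
        assert m.iyy == pytest.approx(iyy, rel=2e-3)

    @pytest.mark.parametrize("winding", [1, -1])
    def test_winding_order_normalized(self, winding):
        v = circle_vertices(1.0, 64)[::winding]
        m = polygon_properties(PolygonOutline(v), (0, 0))
        assert m.area > 0

    def test_monotone_convergence_to_circle(self):
        analytic = math.pi / 4  # unit circle
        values = [
            polygon_properties(PolygonOutline(circle_vertices(1.0, n)), (0, 0)).ixx
            for n in (32, 64, 128, 256, 512)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert all(v < analytic for v in values)
        assert values[-1] == pytest.approx(analytic, rel=1e-3)

    def test_parallel_axis_theorem(self):
        rng = np.random.default_rng(20240917)
        for _ in range(25):
            poly = PolygonOutline(random_star_polygon(rng))
            own = polygon_properties(poly, polygon_properties(poly).centroid)
            ref = rng.uniform(-5, 5, 2)
            shifted = polygon_properties(poly, ref)
            dx = own.centroid[0] - ref[0]
            dy = own.centroid[1] - ref[1]
            assert shifted.ixx == pytest.approx(own.ixx + own.area * dy**2, rel=1e-9)
            assert shifted.iyy == pytest.approx(own.iyy + own.area * dx**2, rel=1e-9)
            assert shifted.ixy == pytest.approx(own.ixy + own.area * dx * dy, rel=1e-9, abs=1e-12)

    def test_rejects_degenerate_outlines(self):
        with pytest.raises(GeometryError, match="3 vertices"):
            PolygonOutline([(0, 0), (1, 1)])
        with pytest.raises(GeometryError, match="zero signed area"):
            PolygonOutline([(0, 0), (1, 1), (2, 2)])
        with pytest.raises(GeometryError, match="self-intersecting"):
            PolygonOutline([(0, 0), (2, 2), (2, 0), (0, 1)])  # crossing edges

    def test_diagnostic_names_offending_outline(self):
        with pytest.raises(GeometryError, match="xylem trace"):
            PolygonOutline([(0, 0), (1, 1)], label="xylem trace")


class TestSectionCentroid:
    def test_single_centered_disc(self):
        sec = CrossSection([TissueRegion("parenchyma", PolygonOutline(circle_vertices(1.0)))])
        assert section_centroid(sec) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_two_adjacent_unit_squares(self):
        a = TissueRegion("sclerenchyma", PolygonOutline([(0, 0), (1, 0), (1, 1), (0, 1)]))
        b = TissueRegion("parenchyma", PolygonOutline([(1, 0), (2, 0), (2, 1), (1, 1)]))
        assert section_centroid(CrossSection([a, b])) == pytest.approx((1.0, 0.5))

    def test_two_equal_discs_midpoint(self):
        a = TissueRegion("sclerenchyma", PolygonOutline(circle_vertices(1.0)))
        b = TissueRegion("parenchyma", PolygonOutline(circle_vertices(1.0, cx=3.0)))
        assert section_centroid(CrossSection([a, b])) == pytest.approx((1.5, 0.0), abs=1e-12)

    def test_independent_of_region_order(self):
        a = TissueRegion("sclerenchyma", PolygonOutline([(0, 0), (1, 0), (1, 1), (0, 1)]))
        b = TissueRegion("parenchyma", PolygonOutline([(1, 0), (3, 0), (3, 1), (1, 1)]))
        assert section_centroid(CrossSection([a, b])) == pytest.approx(
            section_centroid(CrossSection([b, a]))
        )

    def test_empty_section_rejected(self):
        with pytest.raises(GeometryError, match="at least one"):
            CrossSection([])


class TestTissueMoments:
    def test_concentric_annulus_closed_form(self, annulus_section):
        m = tissue_moments(annulus_section)
        assert m.i_x["sclerenchyma"] == pytest.approx(math.pi * (1 - 0.8**4) / 4, rel=1e-3)
        assert m.i_x["parenchyma"] == pytest.approx(math.pi * 0.8**4 / 4, rel=1e-3)
        assert m.total_i_x == pytest.approx(math.pi / 4, rel=1e-3)

    def test_concentric_annulus_grid_oracle(self, annulus_section):
        m = tissue_moments(annulus_section)
        _, _, ixx_st, _, _ = grid_moments(
            lambda X, Y: (X**2 + Y**2 <= 1.0) & (X**2 + Y**2 >= 0.8**2),
            (-1.05, 1.05, -1.05, 1.05),
        )
        _, _, ixx_par, _, _ = grid_moments(
            lambda X, Y: X**2 + Y**2 <= 0.8**2, (-1.05, 1.05, -1.05, 1.05)
        )
        assert m.i_x["sclerenchyma"] == pytest.approx(ixx_st, rel=3e-3)
        assert m.i_x["parenchyma"] == pytest.approx(ixx_par, rel=3e-3)

    def test_single_region_equals_totals(self):
        sec = CrossSection(
            [TissueRegion("xylem", PolygonOutline(circle_vertices(0.5, cx=2.0, cy=1.0)))]
        )
        m = tissue_moments(sec)
        assert m.i_x["xylem"] == m.total_i_x
        assert m.area["xylem"] == m.total_area

    def test_additivity_over_tissues(self, annulus_section):
        m = tissue_moments(annulus_section)
        assert sum(m.i_x.values()) == pytest.approx(m.total_i_x, rel=1e-12)
        assert sum(m.i_y.values()) == pytest.approx(m.total_i_y, rel=1e-12)

    def test_translation_invariance(self, annulus_section):
        m0 = tissue_moments(annulus_section)
        m1 = tissue_moments(annulus_section.translated(5.0, -3.0))
        for tissue in m0.tissues():
            assert m1.area[tissue] == pytest.approx(m0.area[tissue], rel=1e-9)
            assert m1.i_x[tissue] == pytest.approx(m0.i_x[tissue], rel=1e-9)
            assert m1.i_y[tissue] == pytest.approx(m0.i_y[tissue], rel=1e-9)

    def test_rotation_by_90_swaps_axes(self):
        rect = TissueRegion("sclerenchyma", PolygonOutline([(0, 0), (2, 0), (2, 1), (0, 1)]))
        sec = CrossSection([rect])
        m0 = tissue_moments(sec)
        m1 = tissue_moments(sec.rotated90())
        assert m1.total_i_x == pytest.approx(m0.total_i_y, rel=1e-12)
        assert m1.total_i_y == pytest.approx(m0.total_i_x, rel=1e-12)

    def test_rotation_negates_product_moment(self):
        tri = TissueRegion("parenchyma", PolygonOutline([(0, 0), (3, 0), (0, 2)]))
        sec = CrossSection([tri])
        m0 = tissue_moments(sec)
        m1 = tissue_moments(sec.rotated90())
        assert m1.total_i_xy == pytest.approx(-m0.total_i_xy, rel=1e-12)

    def test_hole_equals_difference_of_discs(self):
        outer = PolygonOutline(circle_vertices(1.0))
        inner = PolygonOutline(circle_vertices(0.6))
        annulus = TissueRegion("sclerenchyma", outer, holes=[inner])
        m_hole = annulus.moments_about((0.0, 0.0))
        m_diff_ixx = (
            polygon_properties(outer, (0, 0)).ixx - polygon_properties(inner, (0, 0)).ixx
        )
        assert m_hole.ixx == m_diff_ixx  # exact: identical vertex arithmetic

    def test_overlapping_tissues_rejected_with_names(self):
        a = TissueRegion("sclerenchyma", PolygonOutline(circle_vertices(1.0)))
        b = TissueRegion("parenchyma", PolygonOutline(circle_vertices(0.9)))
        with pytest.raises(GeometryError, match="sclerenchyma.*parenchyma"):
            CrossSection([a, b])

    def test_hole_outside_outer_rejected(self):
        with pytest.raises(GeometryError, match="not strictly inside"):
            TissueRegion(
                "parenchyma",
                PolygonOutline(circle_vertices(1.0)),
                holes=[PolygonOutline(circle_vertices(0.5, cx=2.0))],
            )
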