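import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import rect_geometry, straight_outline
from vsdikit.errors import GeometryError, InvalidParameterError
from vsdikit.geometry import (arc_length_partition, assign_pixels,
                              build_segment_polygons, polyline_arc_length,
                              smooth_midline)


class TestSmoothMidline:
    def test_straight_line_is_fixed_point(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50)])
        out = smooth_midline(pts, 9)
        np.testing.assert_allclose(out, pts, atol=1e-12)

    def test_window_one_is_identity(self, rng):
        pts = rng.normal(size=(30, 2))
        np.testing.assert_array_equal(smooth_midline(pts, 1), pts)

    def test_zigzag_three_point_mean(self):
        n = 9
        x = np.arange(n, dtype=float)
        y = 0.1 * (-1.0) ** np.arange(n)
        out = smooth_midline(np.column_stack([x, y]), 3)
        # interior: mean of (+0.1, -0.1, +0.1) patterns = +/- 1/30
        expected_interior = -y[1:-1] / 3
        np.testing.assert_allclose(out[1:-1, 1], expected_interior, atol=1e-12)
        # endpoints keep their position (window shrinks to a single point)
        assert out[0, 1] == y[0] and out[-1, 1] == y[-1]

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        pts = np.zeros((5, 2))
        with pytest.raises(InvalidParameterError):
            smooth_midline(pts, window)

    @given(st.integers(min_value=0, max_value=2))
    @settings(max_examples=10, deadline=None)
    def test_linear_polylines_invariant_for_any_odd_window(self, half_window_exp):
        window = 2 * (3 ** half_window_exp) + 1
        pts = np.column_stack([np.linspace(-1, 3, 41), np.linspace(5, 2, 41)])
        np.testing.assert_allclose(smooth_midline(pts, window), pts, atol=1e-12)


class TestArcLengthPartition:
    def _line(self, length):
        return np.column_stack([np.linspace(0, length, 200), np.zeros(200)])

    def test_exact_division(self):
        bounds = arc_length_partition(self._line(1.0), 0.1)
        np.testing.assert_allclose(bounds, np.arange(0, 1.05, 0.1), atol=1e-9)
        assert len(bounds) - 1 == 10

    def test_short_tail_merged(self):
        bounds = arc_length_partition(self._line(1.04), 0.1)
        assert len(bounds) - 1 == 10
        np.testing.assert_allclose(bounds[-2:], [0.9, 1.04], atol=1e-9)

    def test_long_tail_kept(self):
        bounds = arc_length_partition(self._line(1.06), 0.1)
        assert len(bounds) - 1 == 11
        np.testing.assert_allclose(bounds[-2:], [1.0, 1.06], atol=1e-9)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            arc_length_partition(self._line(1.0), 0.0)


class TestBuildSegmentPolygons:
    def test_flat_lamina_gives_rectangles(self):
        geom = build_segment_polygons(straight_outline(), 0.1, smooth_window=1)
        assert len(geom) == 10
        np.testing.assert_allclose(geom.areas, 0.05, rtol=1e-9)
        np.testing.assert_allclose(geom.centroids[:, 1], 0.25, atol=1e-9)
        np.testing.assert_allclose(geom.centroids[:, 0],
                                   np.arange(0.05, 1.0, 0.1), atol=1e-9)

    def test_region_labels_follow_transitions(self):
        geom = build_segment_polygons(straight_outline(), 0.1, smooth_window=1)
        assert geom.region_labels == ("hilus",) * 3 + ("CA3",) * 4 + ("CA1",) * 3
        assert geom.region_spans == {"hilus": (0, 3), "CA3": (3, 7), "CA1": (7, 10)}

    def test_annular_wedges_match_closed_form_area(self, quarter_circle_outline):
        arc_len = polyline_arc_length(quarter_circle_outline.midline)[-1]
        w = arc_len / 15
        geom = build_segment_polygons(quarter_circle_outline, w, smooth_window=1)
        assert len(geom) == 15
        wedge = 0.5 * (1.5 ** 2 - 1.0 ** 2) * (np.pi / 2 / 15)
        np.testing.assert_allclose(geom.areas, wedge, rtol=0.02)

    def test_total_area_matches_enclosed_region(self, quarter_circle_outline):
        arc_len = polyline_arc_length(quarter_circle_outline.midline)[-1]
        geom = build_segment_polygons(quarter_circle_outline, arc_len / 15, smooth_window=1)
        total = 0.5 * (1.5 ** 2 - 1.0 ** 2) * (np.pi / 2)
        assert abs(geom.areas.sum() - total) / total < 0.02

    def test_flat_lamina_equal_areas(self):
        geom = build_segment_polygons(straight_outline(length=1.2), 0.1, smooth_window=1)
        assert np.ptp(geom.areas) / geom.areas.mean() < 1e-9

    def test_deterministic(self, quarter_circle_outline):
        arc_len = polyline_arc_length(quarter_circle_outline.midline)[-1]
        g1 = build_segment_polygons(quarter_circle_outline, arc_len / 10, smooth_window=1)
        g2 = build_segment_polygons(quarter_circle_outline, arc_len / 10, smooth_window=1)
        np.testing.assert_array_equal(g1.centroids, g2.centroids)
        np.testing.assert_array_equal(g1.areas, g2.areas)

    def test_missing_boundary_intersection_errors(self):
        # a boundary that stops halfway leaves later radial lines dangling
        out = straight_outline()
        short = out.boundary_a[out.boundary_a[:, 0] < 0.5]
        bad = straight_outline()
        bad = type(out)(midline=out.midline, boundary_a=short, boundary_b=out.boundary_b,
                        transitions_mm=out.transitions_mm, pixel_pitch_mm=out.pixel_pitch_mm)
        with pytest.raises(GeometryError, match="segment boundary"):
            build_segment_polygons(bad, 0.1, smooth_window=1)

    def test_boundary_crossing_midline_is_ambiguous(self):
        out = straight_outline()
        x = np.linspace(-0.05, 1.05, 101)
        crossing = np.column_stack([x, np.linspace(-0.3, 0.3, 101)])
        bad = type(out)(midline=out.midline, boundary_a=crossing, boundary_b=out.boundary_b,
                        transitions_mm=out.transitions_mm, pixel_pitch_mm=out.pixel_pitch_mm)
        with pytest.raises(GeometryError, match="ambiguous"):
            build_segment_polygons(bad, 0.1, smooth_window=1)


class TestAssignPixels:
    def test_rectangle_pixel_count(self):
        geom = rect_geometry(n_segments=1, width=0.1, depth=0.5)
        assignment = assign_pixels(geom, (24, 8), 0.025)
        assert len(assignment.pixels[0]) == 4 * 20

    def test_degenerate_polygon_empty_with_warning(self):
        geom = rect_geometry(n_segments=1, width=0.001, depth=0.001)
        with pytest.warns(UserWarning, match="no pixel centers"):
            assignment = assign_pixels(geom, (10, 10), 0.025)
        assert len(assignment.pixels[0]) == 0
        assert assignment.empty_segments == (0,)

    def test_shared_edge_pixels_go_to_lower_index(self):
        geom = rect_geometry(n_segments=2, width=0.1, depth=0.2,
                             labels=["hilus", "CA1"])
        assignment = assign_pixels(geom, (5, 5), 0.04)
        # centers at x = 0.02, 0.06, 0.10, 0.14, 0.18; x = 0.10 is the shared edge
        xs0 = (assignment.pixels[0][:, 1] + 0.5) * 0.04
        xs1 = (assignment.pixels[1][:, 1] + 0.5) * 0.04
        assert np.isclose(xs0.max(), 0.10)
        assert xs1.min() > 0.10
        all_px = np.vstack([assignment.pixels[0], assignment.pixels[1]])
        assert len(np.unique(all_px, axis=0)) == len(all_px)

    def test_assignment_disjoint_and_within_frame(self, quarter_circle_outline):
        arc_len = polyline_arc_length(quarter_circle_outline.midline)[-1]
        geom = build_segment_polygons(quarter_circle_outline, arc_len / 10, smooth_window=1)
        frame = (70, 70)
        assignment = assign_pixels(geom, frame, 0.025)
        all_px = np.vstack([p for p in assignment.pixels if len(p)])
        assert len(np.unique(all_px, axis=0)) == len(all_px)
        assert all_px.min() >= 0
        assert all_px[:, 0].max() < frame[0] and all_px[:, 1].max() < frame[1]
        assert assignment.n_assigned <= frame[0] * frame[1]


class TestOutlineValidation:
    def test_transitions_must_increase(self):
        with pytest.raises(InvalidParameterError):
            straight_outline(transitions=(0.0, 0.7, 0.3))

    def test_transitions_within_arc(self):
        with pytest.raises(InvalidParameterError):
            straight_outline(transitions=(0.0, 0.5, 2.5))

    def test_positive_pixel_pitch_required(self):
        with pytest.raises(InvalidParameterError):
            straight_outline(pitch=0.0)
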