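"""Anatomy-guided polygonal segmentation of laminar brain-slice geometry.

A slice recording is reduced to a set of wedge-shaped measurement polygons.
The user outlines the cell-body layer (the *midline*), and one boundary
polyline on each side of it (e.g. the outer edge of stratum radiatum and the
stratum oriens side).  The midline is smoothed to remove hand-drawing jitter,
partitioned into fixed-arc-width pieces, and each piece is closed into a
polygon by two radial (locally normal) lines that run from the midline to the
selected boundary.  Region labels (hilus, CA3, CA1) are assigned from
user-marked transition positions along the midline arc.

All geometry lives in millimetres; camera-pixel coordinates appear only in
:func:`assign_pixels`, which maps pixel centers into polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring

from .errors import GeometryError, InvalidParameterError

REGION_ORDER = ("hilus", "CA3", "CA1")

DEFAULT_SMOOTH_WINDOW = 99       # ~0.216 mm of arc for finely drawn lines
DEFAULT_SEGMENT_WIDTH_MM = 0.1


def _as_points(poly) -> np.ndarray:
    pts = np.asarray(poly, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("polyline must be an (N, 2) array of (x, y) mm")
    return pts


def polyline_arc_length(points) -> np.ndarray:
    """Cumulative arc length (mm) at each vertex of a polyline; starts at 0."""
    pts = _as_points(points)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class AnatomyOutline:
    """Hand-drawn slice geometry.

    Parameters
    ----------
    midline
        (N, 2) polyline through the pyramidal cell layer, in mm.
    boundary_a, boundary_b
        Polylines bounding the laminar region on either side of the midline.
    transitions_mm
        Increasing arc-length positions along the midline marking region
        starts: hilus start, hilus->CA3, CA3->CA1.
    pixel_pitch_mm
        Camera pixel width in mm.
    """

    midline: np.ndarray
    boundary_a: np.ndarray
    boundary_b: np.ndarray
    transitions_mm: tuple
    pixel_pitch_mm: float

    def __post_init__(self):
        object.__setattr__(self, "midline", _as_points(self.midline))
        object.__setattr__(self, "boundary_a", _as_points(self.boundary_a))
        object.__setattr__(self, "boundary_b", _as_points(self.boundary_b))
        object.__setattr__(self, "transitions_mm", tuple(float(t) for t in self.transitions_mm))
        if len(self.midline) < 2:
            raise InvalidParameterError("midline needs at least 2 points")
        if self.pixel_pitch_mm <= 0:
            raise InvalidParameterError("pixel_pitch_mm must be > 0")
        total = polyline_arc_length(self.midline)[-1]
        t = np.asarray(self.transitions_mm)
        if len(t) != len(REGION_ORDER):
            raise InvalidParameterError(
                f"expected {len(REGION_ORDER)} transition marks, got {len(t)}"
            )
        if np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > total:
            raise InvalidParameterError(
                "transitions must be strictly increasing within [0, midline arc length]"
            )
        for name in ("boundary_a", "boundary_b"):
            if not LineString(getattr(self, name)).is_simple:
                raise InvalidParameterError(f"{name} self-intersects")

    @property
    def midline_arc_length_mm(self) -> float:
        return float(polyline_arc_length(self.midline)[-1])

    def boundary(self, side: str) -> np.ndarray:
        if side not in ("a", "b"):
            raise InvalidParameterError("side must be 'a' or 'b'")
        return self.boundary_a if side == "a" else self.boundary_b


def smooth_midline(midline, window_points: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Moving-average smoothing of a hand-drawn polyline.

    The window shrinks symmetrically near the ends (the endpoint itself is
    averaged over a single point), which keeps the polyline endpoints fixed
    instead of dragging them toward the origin as zero-padding would.
    """
    if window_points < 1 or window_points % 2 == 0:
        raise InvalidParameterError("window_points must be an odd integer >= 1")
    pts = _as_points(midline)
    n = len(pts)
    if window_points == 1 or n < 3:
        return pts.copy()
    half = window_points // 2
    # prefix sums give O(n) symmetric-shrinking-window means
    csum = np.vstack([np.zeros(2), np.cumsum(pts, axis=0)])
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return out


def arc_length_partition(midline, width_mm: float, start_mm: float = 0.0) -> np.ndarray:
    """Arc positions of segment boundaries along the midline.

    Boundaries fall at ``start, start+w, start+2w, ...`` plus the terminal arc
    length.  A final partial segment shorter than ``w/2`` is merged into its
    predecessor so that no near-zero-area segment is produced.
    """
    if width_mm <= 0:
        raise InvalidParameterError("width_mm must be > 0")
    total = float(polyline_arc_length(midline)[-1])
    span = total - start_mm
    if span < width_mm:
        raise InvalidParameterError("midline arc shorter than one segment width")
    eps = 1e-9 * max(total, 1.0)
    n_full = int(np.floor(span / width_mm + eps))
    bounds = start_mm + width_mm * np.arange(n_full + 1)
    remainder = total - bounds[-1]
    if remainder > eps:
        if remainder < width_mm / 2 and n_full >= 1:
            bounds = bounds[:-1]          # merge the short tail into the last segment
        bounds = np.append(bounds, total)
    else:
        bounds[-1] = total
    return bounds


def _point_and_tangent(pts: np.ndarray, arcs: np.ndarray, s: float):
    """Interpolated point and unit tangent of a polyline at arc position s."""
    s = float(np.clip(s, arcs[0], arcs[-1]))
    i = int(np.clip(np.searchsorted(arcs, s, side="right") - 1, 0, len(pts) - 2))
    seg = pts[i + 1] - pts[i]
    seg_len = arcs[i + 1] - arcs[i]
    frac = 0.0 if seg_len == 0 else (s - arcs[i]) / seg_len
    p = pts[i] + frac * seg
    # tangent by central differences at vertices, blended across the segment
    t0 = _vertex_tangent(pts, i)
    t1 = _vertex_tangent(pts, i + 1)
    t = (1 - frac) * t0 + frac * t1
    norm = np.linalg.norm(t)
    if norm == 0:
        raise GeometryError(f"degenerate midline tangent at arc {s:.4f} mm")
    return p, t / norm


def _vertex_tangent(pts: np.ndarray, i: int) -> np.ndarray:
    j0, j1 = max(i - 1, 0), min(i + 1, len(pts) - 1)
    d = pts[j1] - pts[j0]
    n = np.linalg.norm(d)
    return d / n if n > 0 else d


def _normal_sign(midline: np.ndarray, arcs: np.ndarray, boundary: np.ndarray) -> float:
    """Which side of the midline the boundary lies on (+1 left of tangent, -1 right).

    Every boundary vertex must fall on the same side; a boundary that crosses
    the midline is ambiguous and rejected.
    """
    line = LineString(midline)
    signs = []
    for v in boundary:
        s = line.project(Point(v))
        p, t = _point_and_tangent(midline, arcs, s)
        cross = t[0] * (v[1] - p[1]) - t[1] * (v[0] - p[0])
        if abs(cross) > 1e-12:
            signs.append(np.sign(cross))
    if not signs:
        raise GeometryError("boundary polyline coincides with the midline")
    if len(set(signs)) > 1:
        raise GeometryError("boundary polyline crosses the midline; side is ambiguous")
    return signs[0]


@dataclass(frozen=True)
class SegmentedGeometry:
    """Ordered fixed-arc-width measurement polygons along a laminar midline."""

    polygons: tuple            # shapely Polygons, ordered by increasing arc
    region_labels: tuple       # one of REGION_ORDER per segment
    centroids: np.ndarray      # (n, 2) mm
    areas: np.ndarray          # (n,) mm^2
    segment_width_mm: float
    arc_spans: np.ndarray      # (n, 2) start/end arc position of each segment
    midline: np.ndarray = field(default=None, repr=False)  # smoothed midline actually used

    def __post_init__(self):
        n = len(self.polygons)
        if not (len(self.region_labels) == len(self.centroids) == len(self.areas) == n):
            raise InvalidParameterError("segment metadata lengths disagree")
        if np.any(np.asarray(self.areas) <= 0):
            raise GeometryError("every segment polygon must have positive area")

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def region_spans(self) -> dict:
        """Row index span (start, stop) per region, in midline order."""
        labels = np.asarray(self.region_labels)
        spans = {}
        for region in REGION_ORDER:
            idx = np.flatnonzero(labels == region)
            if idx.size:
                spans[region] = (int(idx[0]), int(idx[-1]) + 1)
        return spans

    @classmethod
    def from_polygons(cls, polygons, region_labels, segment_width_mm=float("nan"),
                      arc_spans=None, midline=None):
        polys = tuple(Polygon(p) if not isinstance(p, Polygon) else p for p in polygons)
        centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])
        areas = np.array([p.area for p in polys])
        if arc_spans is None:
            arc_spans = np.full((len(polys), 2), np.nan)
        return cls(polys, tuple(region_labels), centroids, areas,
                   segment_width_mm, np.asarray(arc_spans), midline)


def build_segment_polygons(outline: AnatomyOutline, width_mm: float = DEFAULT_SEGMENT_WIDTH_MM,
                           side: str = "a", smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                           ) -> SegmentedGeometry:
    """Partition the laminar region into fixed-arc-width polygons.

    The midline is smoothed, partitioned at fixed arc intervals starting from
    the first transition mark, and each partition boundary is extended along
    the local midline normal until it first meets the boundary polyline chosen
    by ``side``.  Each segment polygon is bounded by two consecutive radial
    lines, the midline arc between them, and the boundary arc between the two
    intersection points.
    """
    boundary_pts = outline.boundary(side)
    midline = smooth_midline(outline.midline, smooth_window)
    arcs = polyline_arc_length(midline)
    bounds = arc_length_partition(midline, width_mm, start_mm=outline.transitions_mm[0])

    sign = _normal_sign(midline, arcs, boundary_pts)
    boundary_line = LineString(boundary_pts)
    span = max(np.ptp(midline, axis=0).max(), np.ptp(boundary_pts, axis=0).max())
    ray_len = 10.0 * max(span, 1.0)

    mid_pts, hits, hit_u = [], [], []
    for k, s in enumerate(bounds):
        p, t = _point_and_tangent(midline, arcs, s)
        normal = sign * np.array([-t[1], t[0]])
        ray = LineString([p, p + ray_len * normal])
        inter = ray.intersection(boundary_line)
        if inter.is_empty:
            raise GeometryError(f"radial line at segment boundary {k} misses the region boundary")
        q = _nearest_point(inter, p)
        mid_pts.append(p)
        hits.append(q)
        hit_u.append(boundary_line.project(Point(q)))

    midline_ls = LineString(midline)
    polygons, labels, spans = [], [], []
    transitions = np.asarray(outline.transitions_mm)
    for k in range(len(bounds) - 1):
        s0, s1 = bounds[k], bounds[k + 1]
        mid_arc = np.asarray(substring(midline_ls, s0, s1).coords)
        u0, u1 = hit_u[k], hit_u[k + 1]
        # the substring endpoints are the radial-line hit points; taking them
        # from the substring itself keeps every ring vertex on one polyline and
        # avoids degenerate float-noise spikes at the corners
        bnd_arc = np.asarray(substring(boundary_line, u1, u0).coords)
        poly = Polygon(np.vstack([mid_arc, bnd_arc]))
        if not poly.is_valid:
            raise GeometryError(f"segment {k} polygon is self-intersecting")
        if poly.area <= 0:
            raise GeometryError(f"segment {k} polygon has zero area")
        polygons.append(poly)
        mid = 0.5 * (s0 + s1)
        region_idx = int(np.searchsorted(transitions, mid, side="right") - 1)
        labels.append(REGION_ORDER[min(max(region_idx, 0), len(REGION_ORDER) - 1)])
        spans.append((s0, s1))

    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polygons])
    areas = np.array([p.area for p in polygons])
    return SegmentedGeometry(tuple(polygons), tuple(labels), centroids, areas,
                             float(width_mm), np.asarray(spans), midline)


def _nearest_point(geom, origin: np.ndarray) -> np.ndarray:
    """First intersection along the ray = intersection point nearest the origin."""
    pts = []
    for g in getattr(geom, "geoms", [geom]):
        pts.extend(np.asarray(g.coords))
    pts = np.asarray(pts)
    d = np.linalg.norm(pts - origin, axis=1)
    return pts[int(np.argmin(d))]


@dataclass(frozen=True)
class PixelAssignment:
    """Camera pixels grouped by the measurement polygon containing their center."""

    pixels: tuple              # per segment: (k_i, 2) int array of (row, col)
    frame_shape: tuple
    empty_segments: tuple = ()

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def n_assigned(self) -> int:
        return int(sum(len(p) for p in self.pixels))


def assign_pixels(geometry: SegmentedGeometry, frame_shape, pixel_pitch_mm: float,
                  ) -> PixelAssignment:
    """Assign each camera pixel to the polygon containing its center.

    Pixel (row, col) has its center at ((col+0.5)*pitch, (row+0.5)*pitch) mm.
    A center lying exactly on a shared polygon edge goes to the lower segment
    index; centers outside every polygon stay unassigned.  Segments too small
    to contain any pixel center come back empty with a warning.
    """
    if pixel_pitch_mm <= 0:
        raise InvalidParameterError("pixel_pitch_mm must be > 0")
    ny, nx = frame_shape
    taken = np.zeros((ny, nx), dtype=bool)
    out, empty = [], []
    for k, poly in enumerate(geometry.polygons):
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.floor(minx / pixel_pitch_mm - 0.5)), 0)
        c1 = min(int(np.ceil(maxx / pixel_pitch_mm - 0.5)) + 1, nx)
        r0 = max(int(np.floor(miny / pixel_pitch_mm - 0.5)), 0)
        r1 = min(int(np.ceil(maxy / pixel_pitch_mm - 0.5)) + 1, ny)
        if c1 <= c0 or r1 <= r0:
            out.append(np.empty((0, 2), dtype=int))
            empty.append(k)
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        rows, cols = rows.ravel(), cols.ravel()
        xs = (cols + 0.5) * pixel_pitch_mm
        ys = (rows + 0.5) * pixel_pitch_mm
        inside = shapely.covers(poly, shapely.points(xs, ys))  # boundary-inclusive
        inside &= ~taken[rows, cols]
        sel = np.column_stack([rows[inside], cols[inside]])
        taken[sel[:, 0], sel[:, 1]] = True
        out.append(sel)
        if len(sel) == 0:
            empty.append(k)
    if empty:
        warnings.warn(f"{len(empty)} segment(s) contain no pixel centers: {empty[:10]}",
                      stacklevel=2)
    return PixelAssignment(tuple(out), (ny, nx), tuple(empty))


def segment_slice(outline: AnatomyOutline, width_mm: float = DEFAULT_SEGMENT_WIDTH_MM,
                  side: str = "a", frame_shape=None,
                  smooth_window: int = DEFAULT_SMOOTH_WINDOW):
    """Convenience: smooth, segment, and (optionally) assign pixels in one call."""
    geometry = build_segment_polygons(outline, width_mm, side, smooth_window)
    if frame_shape is None:
        return geometry
    assignment = assign_pixels(geometry, frame_shape, outline.pixel_pitch_mm)
    return geometry, assignment
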