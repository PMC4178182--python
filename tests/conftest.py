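import numpy as np
import pytest
from shapely.geometry import box

from vsdikit.geometry import AnatomyOutline, SegmentedGeometry
from vsdikit.transform import Raster


def straight_outline(length=1.0, depth=0.5, n_pts=101, overhang=0.05,
                     transitions=(0.0, 0.3, 0.7), pitch=0.025):
    """Horizontal midline y=0 from x=0..length, boundary_a at y=depth."""
    x = np.linspace(0.0, length, n_pts)
    xb = np.linspace(-overhang, length + overhang, n_pts)
    return AnatomyOutline(
        midline=np.column_stack([x, np.zeros_like(x)]),
        boundary_a=np.column_stack([xb, np.full_like(xb, depth)]),
        boundary_b=np.column_stack([xb, np.full_like(xb, -depth)]),
        transitions_mm=transitions,
        pixel_pitch_mm=pitch,
    )


def rect_geometry(n_segments=10, width=0.1, depth=0.5, labels=None):
    """Axis-aligned rectangle segments [k*w, (k+1)*w] x [0, depth]."""
    polys = [box(k * width, 0.0, (k + 1) * width, depth) for k in range(n_segments)]
    if labels is None:
        labels = (["hilus"] + ["CA3"] * (n_segments - 2) + ["CA1"])[:n_segments]
        labels += ["CA1"] * (n_segments - len(labels))
    spans = np.array([[k * width, (k + 1) * width] for k in range(n_segments)])
    midline = np.column_stack([np.linspace(0, n_segments * width, 50), np.zeros(50)])
    return SegmentedGeometry.from_polygons(polys, labels, segment_width_mm=width,
                                           arc_spans=spans, midline=midline)


def make_test_raster(values, spans=None, t0_frame=0, frame_rate=500.0):
    values = np.asarray(values, dtype=float)
    n_rows, n_frames = values.shape
    if spans is None:
        spans = {"hilus": (0, 1), "CA3": (1, max(n_rows - 1, 2)), "CA1": (max(n_rows - 1, 2), n_rows)}
    time_ms = (np.arange(n_frames) - t0_frame) * 1000.0 / frame_rate
    return Raster(values=values, region_spans=spans, time_ms=time_ms)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quarter_circle_outline():
    """Concentric arcs: midline radius 1.0, outer boundary radius 1.5."""
    theta = np.linspace(0.0, np.pi / 2, 2000)
    theta_b = np.linspace(-0.02, np.pi / 2 + 0.02, 2000)
    mid = np.column_stack([np.cos(theta), np.sin(theta)])
    outer = 1.5 * np.column_stack([np.cos(theta_b), np.sin(theta_b)])
    inner = 0.8 * np.column_stack([np.cos(theta_b), np.sin(theta_b)])
    arc_len = np.pi / 2
    return AnatomyOutline(midline=mid, boundary_a=outer, boundary_b=inner,
                          transitions_mm=(0.0, 0.3 * arc_len, 0.7 * arc_len),
                          pixel_pitch_mm=0.025)
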