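"""Quantitative comparison of slice anatomy between groups.

Two per-slice measures are taken from the original, never-stretched geometry:
the arc length of the (smoothed) cell-layer midline and the total area of the
measurement polygons.  Groups are compared metric by metric with Welch's
unequal-variance t-test, reporting the percent difference of group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError
from .geometry import AnatomyOutline, SegmentedGeometry, polyline_arc_length

METRICS = ("midline_length_mm", "raster_area_mm2")


@dataclass(frozen=True)
class SliceMorphometry:
    midline_length_mm: float
    raster_area_mm2: float
    group: str = ""
    slice_id: str = ""

    def __post_init__(self):
        if self.midline_length_mm <= 0 or self.raster_area_mm2 <= 0:
            raise InvalidParameterError("morphometric measures must be positive")


def measure_morphometry(geometry: SegmentedGeometry, outline: AnatomyOutline = None,
                        group: str = "", slice_id: str = "") -> SliceMorphometry:
    """Midline arc length and summed polygon area of one slice geometry.

    Uses the smoothed midline stored on the geometry when available, falling
    back to the outline's raw midline.
    """
    midline = geometry.midline if geometry.midline is not None else (
        outline.midline if outline is not None else None)
    if midline is None:
        raise InvalidParameterError("no midline available on geometry or outline")
    return SliceMorphometry(
        midline_length_mm=float(polyline_arc_length(midline)[-1]),
        raster_area_mm2=float(np.sum(geometry.areas)),
        group=group, slice_id=slice_id,
    )


@dataclass(frozen=True)
class MorphometryComparison:
    p_values: dict               # metric -> Welch p
    percent_difference: dict     # metric -> 100*(mean_b - mean_a)/mean_a
    means_a: dict
    means_b: dict


def compare_morphometry(group_a, group_b) -> MorphometryComparison:
    """Per-metric Welch t-test and percent difference between two slice groups."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise InvalidParameterError("each group needs at least 2 slices")
    p, pct, ma, mb = {}, {}, {}, {}
    for metric in METRICS:
        a = np.array([getattr(m, metric) for m in group_a])
        b = np.array([getattr(m, metric) for m in group_b])
        ma[metric], mb[metric] = float(a.mean()), float(b.mean())
        pct[metric] = 100.0 * (b.mean() - a.mean()) / a.mean()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p[metric] = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        else:
            p[metric] = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    return MorphometryComparison(p_values=p, percent_difference=pct,
                                 means_a=ma, means_b=mb)
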