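"""Propagation velocity of evoked activity along the laminar segment path.

Each selected raster row's *activation time* is the time of the maximal first
derivative of its dF/F trace inside a post-stimulus search window.  Distances
are cumulative Euclidean gaps between consecutive segment centroids, measured
on the original (never stretched) geometry so real-world units are preserved.
The velocity is the slope of an ordinary least-squares fit of distance (mm)
on time (ms), which is numerically equal to m/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError, NoActivationError
from .geometry import SegmentedGeometry
from .transform import Raster


@dataclass(frozen=True)
class VelocityFit:
    activation_times_ms: np.ndarray
    distances_mm: np.ndarray
    velocity_m_per_s: float
    r_squared: float
    intercept_mm: float
    rows_used: tuple


def activation_time(signal, time_ms, search_window) -> float:
    """Time (ms) of the maximal first derivative within the search window.

    The derivative is taken by central differences on the (already median
    filtered) trace; ties break toward the earliest frame.  A window with no
    derivative structure (flat signal) raises :class:`NoActivationError`.
    """
    signal = np.asarray(signal, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    lo, hi = search_window
    if hi - lo < 3:
        raise InvalidParameterError("search window must span at least 3 frames")
    if lo < 0 or hi > signal.size:
        raise InvalidParameterError("search window exceeds the signal length")
    seg, t = signal[lo:hi], time_ms[lo:hi]
    deriv = np.gradient(seg, t)
    if np.allclose(deriv, 0.0):
        raise NoActivationError("signal is flat inside the search window")
    return float(t[int(np.argmax(deriv))])


def centroid_distances(geometry: SegmentedGeometry, rows) -> np.ndarray:
    """Cumulative centroid-to-centroid Euclidean distance along the selected rows."""
    rows = np.asarray(rows, dtype=int)
    if rows.size < 2:
        raise InvalidParameterError("need at least 2 rows to measure distances")
    pts = geometry.centroids[rows]
    gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(gaps)])


def fit_velocity(times_ms, distances_mm, rows_used=()) -> VelocityFit:
    """Ordinary least squares of distance (mm) on activation time (ms).

    The slope in mm/ms equals the velocity in m/s.
    """
    t = np.asarray(times_ms, dtype=float)
    d = np.asarray(distances_mm, dtype=float)
    if t.size != d.size or t.size < 3:
        raise InvalidParameterError("need at least 3 (time, distance) points")
    if np.ptp(t) == 0:
        raise InvalidParameterError("activation times have zero variance; cannot fit")
    res = sps.linregress(t, d)
    return VelocityFit(
        activation_times_ms=t, distances_mm=d,
        velocity_m_per_s=float(res.slope), r_squared=float(res.rvalue ** 2),
        intercept_mm=float(res.intercept), rows_used=tuple(rows_used),
    )


def measure_velocity(raster: Raster, geometry: SegmentedGeometry, rows,
                     search_window) -> VelocityFit:
    """Activation times for the selected rows of an un-stretched raster, then the fit."""
    if raster.standardized:
        raise InvalidParameterError(
            "velocity must be measured on an un-stretched raster (real-world units)"
        )
    rows = np.asarray(rows, dtype=int)
    times = np.array([activation_time(raster.values[r], raster.time_ms, search_window)
                      for r in rows])
    distances = centroid_distances(geometry, rows)
    return fit_velocity(times, distances, rows_used=rows)
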