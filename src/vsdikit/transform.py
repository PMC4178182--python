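"""Movie -> raster transformation.

A movie (time x y x x fluorescence counts) is reduced to a 2D *raster*:
one row per polygonal measurement segment, one column per camera frame,
holding the segment-averaged fractional fluorescence change dF/F.  Processing
order is: per-pixel dF/F against a pre-stimulus baseline, unweighted average
over each segment's pixels, then a short running median along time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, ZeroBaselineError
from .geometry import PixelAssignment, SegmentedGeometry

DEFAULT_FRAME_RATE_HZ = 500.0
DEFAULT_MEDIAN_WIDTH_MS = 10.0


@dataclass(frozen=True)
class Movie:
    """Raw fluorescence frame stack with acquisition metadata.

    ``stimulus_frame`` is the index of t = 0; frames before it form the
    pre-stimulus baseline.
    """

    frames: np.ndarray                      # (n_frames, ny, nx)
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    stimulus_frame: int = 0
    pixel_pitch_mm: float = 0.025

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise InvalidParameterError("frames must be a (time, y, x) array")
        object.__setattr__(self, "frames", frames)
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame_rate_hz must be > 0")
        if not (1 <= self.stimulus_frame <= len(frames) - 1):
            raise InvalidParameterError(
                "stimulus_frame must leave at least one pre-stimulus baseline frame"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def time_ms(self) -> np.ndarray:
        """Per-frame time relative to the stimulus, in ms."""
        return (np.arange(self.n_frames) - self.stimulus_frame) * 1000.0 / self.frame_rate_hz


@dataclass(frozen=True)
class Raster:
    """2D spatiotemporal map: segment row x time frame, values are dF/F.

    Row 0 is the hilus end of the midline; rows proceed through CA3 to CA1.
    Inter-region divider rows are a rendering artifact and never stored here.
    """

    values: np.ndarray                      # (n_rows, n_frames)
    region_spans: dict                      # region -> (start, stop) row index
    time_ms: np.ndarray
    geometry: SegmentedGeometry = field(default=None, repr=False)
    standardized: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "time_ms", np.asarray(self.time_ms, dtype=float))
        if values.ndim != 2:
            raise InvalidParameterError("raster values must be 2D (rows x frames)")
        if values.shape[1] != len(self.time_ms):
            raise InvalidParameterError("time_ms length must equal the frame count")
        stop_prev = 0
        for region, (start, stop) in self.region_spans.items():
            if start != stop_prev or stop <= start:
                raise InvalidParameterError("region_spans must partition rows in order")
            stop_prev = stop
        if stop_prev != values.shape[0]:
            raise InvalidParameterError("region_spans do not cover all raster rows")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def region_rows(self, region: str) -> np.ndarray:
        start, stop = self.region_spans[region]
        return np.arange(start, stop)


def compute_dff(movie: Movie, baseline_frames=None, sign: int = 1) -> np.ndarray:
    """Per-pixel fractional fluorescence change against a baseline mean.

    dF/F_t = sign * (F_t - F0) / F0 with F0 the pixel's mean over
    ``baseline_frames`` (default: every pre-stimulus frame).  ``sign=-1``
    renders depolarization positive for dyes whose fluorescence decreases
    with depolarization.
    """
    if sign not in (1, -1):
        raise InvalidParameterError("sign must be +1 or -1")
    if baseline_frames is None:
        baseline_frames = np.arange(movie.stimulus_frame)
    baseline_frames = np.asarray(baseline_frames)
    if baseline_frames.size == 0:
        raise InvalidParameterError("baseline_frames must be non-empty")
    if baseline_frames.min() < 0 or baseline_frames.max() >= movie.stimulus_frame:
        raise InvalidParameterError("baseline_frames must lie before the stimulus frame")
    f0 = movie.frames[baseline_frames].mean(axis=0)
    zero = np.argwhere(f0 == 0)
    if len(zero):
        r, c = zero[0]
        raise ZeroBaselineError(f"baseline fluorescence is zero at pixel (row={r}, col={c})")
    return sign * (movie.frames - f0) / f0


def polygon_average(dff: np.ndarray, assignment: PixelAssignment) -> np.ndarray:
    """Unweighted mean dF/F over each segment's pixel centers, per frame.

    Returns an (n_segments, n_frames) array; empty segments yield NaN rows.
    """
    if dff.shape[1:] != tuple(assignment.frame_shape):
        raise InvalidParameterError("dF/F frame shape does not match the pixel assignment")
    n_frames = dff.shape[0]
    out = np.full((len(assignment), n_frames), np.nan)
    for k, px in enumerate(assignment.pixels):
        if len(px):
            out[k] = dff[:, px[:, 0], px[:, 1]].mean(axis=1)
    if assignment.empty_segments:
        warnings.warn(
            f"empty segments produce NaN raster rows: {list(assignment.empty_segments)[:10]}",
            stacklevel=2,
        )
    return out


def median_filter_width(width_ms: float, frame_rate_hz: float) -> int:
    """Median window length in frames: nearest odd integer >= 1 (even rounds up)."""
    if width_ms <= 0:
        raise InvalidParameterError("width_ms must be > 0")
    w = max(int(round(width_ms * frame_rate_hz / 1000.0)), 1)
    return w + 1 if w % 2 == 0 else w


def median_filter_time(signals: np.ndarray, width_ms: float = DEFAULT_MEDIAN_WIDTH_MS,
                       frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> np.ndarray:
    """Running median along time for every row, edges by symmetric shrinking window."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    w = median_filter_width(width_ms, frame_rate_hz)
    n = signals.shape[1]
    if w == 1 or n == 1:
        return signals.copy()
    half = w // 2
    out = np.empty_like(signals)
    if n >= w:
        windows = np.lib.stride_tricks.sliding_window_view(signals, w, axis=1)
        out[:, half:n - half] = np.median(windows, axis=2)
    for i in range(min(half, n)):
        h = min(i, n - 1 - i, half)
        out[:, i] = np.median(signals[:, i - h:i + h + 1], axis=1)
        j = n - 1 - i
        h = min(j, n - 1 - j, half)
        out[:, j] = np.median(signals[:, j - h:j + h + 1], axis=1)
    return out


def build_raster(movie: Movie, geometry: SegmentedGeometry, assignment: PixelAssignment,
                 *, baseline_frames=None, sign: int = 1,
                 median_width_ms: float = DEFAULT_MEDIAN_WIDTH_MS,
                 dff: np.ndarray = None) -> Raster:
    """Full movie -> raster pipeline: dF/F, polygon averaging, temporal median.

    A precomputed ``dff`` array may be supplied to avoid recomputing it when
    one movie is segmented at several widths.
    """
    if dff is None:
        dff = compute_dff(movie, baseline_frames, sign)
    averaged = polygon_average(dff, assignment)
    filtered = median_filter_time(averaged, median_width_ms, movie.frame_rate_hz)
    return Raster(values=filtered, region_spans=geometry.region_spans,
                  time_ms=movie.time_ms, geometry=geometry)
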