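"""Synthetic VSDI data with known ground truth.

Emulates a curved or straight laminar region (hilus -> CA3 -> CA1 along the
midline arc) responding to a stimulus with a fast EPSP-like depolarization
(double-exponential kinetics), an optional slow hyperpolarization, an optional
travelling activation wave of known velocity, and additive i.i.d. Gaussian
noise on top of per-pixel baseline fluorescence with staining heterogeneity.
Every generated object carries its ground truth, and everything is
deterministic under the spec's seed, so the rest of the toolbox is testable
without any recorded data.

The generator's defaults are the study conditions used throughout the test
suite: a 3.3 mm lamina split 0.3/1.8/1.2 mm between hilus/CA3/CA1 (matching
the 4/24/16 standard-row proportions), 0.025 mm pixels, 500 frames/s, 301
frames with the stimulus at frame 50, a 3% dF/F EPSP (2 ms rise, 10 ms decay),
a 0.5% slow hyperpolarization, and pixel noise SD 0.003.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coalign import StandardGrid, standardize_raster
from .errors import InvalidParameterError
from .geometry import (REGION_ORDER, AnatomyOutline, assign_pixels,
                       build_segment_polygons)
from .transform import Movie, Raster, build_raster


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic slice recording."""

    shape: str = "straight"               # "straight" or "arc"
    arc_radius_mm: float = 2.2
    midline_length_mm: float = 3.3
    lamina_width_mm: float = 0.3          # midline-to-boundary offset, both sides
    margin_mm: float = 0.1
    region_fractions: tuple = (1 / 11, 6 / 11, 4 / 11)   # hilus, CA3, CA1
    point_spacing_mm: float = 0.0022      # hand-drawn-line vertex spacing
    pixel_pitch_mm: float = 0.025
    frame_rate_hz: float = 500.0
    n_frames: int = 301
    stimulus_frame: int = 50
    baseline_f0: float = 1000.0
    f0_jitter: float = 0.1                # per-pixel staining heterogeneity (lognormal sd)
    epsp_amplitude: float = 0.03          # peak dF/F of the fast depolarization
    epsp_rise_ms: float = 2.0
    epsp_decay_ms: float = 10.0
    ipsp_amplitude: float = 0.005         # slow hyperpolarization magnitude
    ipsp_rise_ms: float = 20.0
    ipsp_decay_ms: float = 100.0
    wave_velocity_m_per_s: float = None   # None: synchronous onset everywhere
    noise_sd: float = 0.003               # i.i.d. Gaussian pixel noise on dF/F
    amplitude_jitter: float = 0.1         # slice-to-slice lognormal amplitude sd
    region_amp_scale: dict = field(default_factory=dict)  # e.g. {"CA1": 0.5}
    seed: int = 0

    def __post_init__(self):
        if self.shape not in ("straight", "arc"):
            raise InvalidParameterError("shape must be 'straight' or 'arc'")
        if abs(sum(self.region_fractions) - 1.0) > 1e-9 or len(self.region_fractions) != 3:
            raise InvalidParameterError("region_fractions must be 3 values summing to 1")
        if self.seed is None:
            raise InvalidParameterError("a seed is mandatory for reproducibility")


def make_geometry(spec: SynthSpec) -> AnatomyOutline:
    """Deterministic outline: midline, two offset boundaries, transition marks."""
    n_pts = max(int(round(spec.midline_length_mm / spec.point_spacing_mm)) + 1, 2)
    s = np.linspace(0.0, spec.midline_length_mm, n_pts)
    w, m = spec.lamina_width_mm, spec.margin_mm
    # boundaries overhang the midline ends, as hand-drawn outlines do, so the
    # terminal radial lines always find an intersection
    ext = m / 2
    s_b = np.linspace(-ext, spec.midline_length_mm + ext, n_pts)
    if spec.shape == "straight":
        y0 = m + w
        midline = np.column_stack([m + s, np.full_like(s, y0)])
        boundary_a = np.column_stack([m + s_b, np.full_like(s_b, y0 + w)])
        boundary_b = np.column_stack([m + s_b, np.full_like(s_b, y0 - w)])
    else:
        r = spec.arc_radius_mm
        if spec.midline_length_mm + 2 * ext > np.pi * r:
            raise InvalidParameterError("arc lamina longer than a half circle")
        cx, cy = m + r + w, m + r + w
        def ring(radius, arc):
            theta = np.pi + arc / r    # sweep counter-clockwise from the left
            return np.column_stack([cx + radius * np.cos(theta),
                                    cy + radius * np.sin(theta)])
        midline = ring(r, s)
        boundary_a, boundary_b = ring(r + w, s_b), ring(r - w, s_b)
    f1, f2, _ = spec.region_fractions
    length = spec.midline_length_mm
    transitions = (0.0, f1 * length, (f1 + f2) * length)
    return AnatomyOutline(midline=midline, boundary_a=boundary_a, boundary_b=boundary_b,
                          transitions_mm=transitions, pixel_pitch_mm=spec.pixel_pitch_mm)


def _normalized_envelope(t_ms: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """(1 - exp(-t/rise)) * exp(-t/decay) for t > 0, scaled to unit peak."""
    t_peak = rise * np.log1p(decay / rise)
    peak = (1 - np.exp(-t_peak / rise)) * np.exp(-t_peak / decay)
    tp = np.maximum(t_ms, 0.0)
    env = (1 - np.exp(-tp / rise)) * np.exp(-tp / decay) / peak
    return np.where(t_ms > 0, env, 0.0)


def _region_of_arc(spec: SynthSpec, s: np.ndarray) -> np.ndarray:
    f1, f2, _ = spec.region_fractions
    length = spec.midline_length_mm
    out = np.full(s.shape, 1, dtype=int)          # CA3
    out[s < f1 * length] = 0                      # hilus
    out[s >= (f1 + f2) * length] = 2              # CA1
    return out


@dataclass(frozen=True)
class MovieTruth:
    """Ground truth accompanying a synthetic movie."""

    spec: SynthSpec
    slice_scale: float                 # realized slice-wide amplitude factor
    dff_peak_by_region: dict           # region -> true peak dF/F
    wave_velocity_m_per_s: float       # None if onset is synchronous

    def activation_delay_ms(self, arc_mm) -> np.ndarray:
        """True onset delay at the given midline arc positions."""
        arc = np.asarray(arc_mm, dtype=float)
        if self.wave_velocity_m_per_s is None:
            return np.zeros_like(arc)
        return arc / self.wave_velocity_m_per_s   # mm / (mm/ms) = ms


def make_movie(spec: SynthSpec, outline: AnatomyOutline = None,
               seed: int = None) -> tuple:
    """Synthesize one recording: (Movie, MovieTruth).

    The evoked field lives between the midline and boundary_a ("side a");
    noise covers the whole frame.  Raw counts are
    F = F0_pixel * (1 + dF/F_true + noise).
    """
    if outline is None:
        outline = make_geometry(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    w, m, length = spec.lamina_width_mm, spec.margin_mm, spec.midline_length_mm

    if spec.shape == "straight":
        nx = int(np.ceil((2 * m + length) / spec.pixel_pitch_mm))
        ny = int(np.ceil((2 * m + 2 * w) / spec.pixel_pitch_mm))
    else:
        r = spec.arc_radius_mm
        extent = 2 * (m + r + w)
        nx = ny = int(np.ceil(extent / spec.pixel_pitch_mm))
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    xs = (cols + 0.5) * spec.pixel_pitch_mm
    ys = (rows + 0.5) * spec.pixel_pitch_mm

    if spec.shape == "straight":
        y0 = m + w
        s = xs - m
        inside = (s >= 0) & (s <= length) & (ys >= y0) & (ys <= y0 + w)
    else:
        r = spec.arc_radius_mm
        cx = cy = m + r + w
        rad = np.hypot(xs - cx, ys - cy)
        theta = np.mod(np.arctan2(ys - cy, xs - cx) - np.pi, 2 * np.pi)
        s = theta * r
        inside = (rad >= r) & (rad <= r + w) & (s >= 0) & (s <= length)

    slice_scale = float(np.exp(rng.normal(0.0, spec.amplitude_jitter)))
    region_idx = _region_of_arc(spec, s[inside])
    region_scale = np.array([spec.region_amp_scale.get(name, 1.0) for name in REGION_ORDER])
    amp = spec.epsp_amplitude * slice_scale * region_scale[region_idx]

    time_ms = (np.arange(spec.n_frames) - spec.stimulus_frame) * 1000.0 / spec.frame_rate_hz
    if spec.wave_velocity_m_per_s is not None:
        delay = s[inside] / spec.wave_velocity_m_per_s
    else:
        delay = np.zeros(int(inside.sum()))
    t_rel = time_ms[None, :] - delay[:, None]
    sig = amp[:, None] * _normalized_envelope(t_rel, spec.epsp_rise_ms, spec.epsp_decay_ms)
    if spec.ipsp_amplitude:
        sig = sig - (spec.ipsp_amplitude * slice_scale
                     * _normalized_envelope(t_rel, spec.ipsp_rise_ms, spec.ipsp_decay_ms))

    dff_true = np.zeros((spec.n_frames, ny, nx))
    dff_true[:, inside] = sig.T
    if spec.noise_sd:
        dff_true = dff_true + rng.normal(0.0, spec.noise_sd, dff_true.shape)
    f0 = spec.baseline_f0 * np.exp(rng.normal(0.0, spec.f0_jitter, (ny, nx)))
    frames = f0 * (1.0 + dff_true)

    movie = Movie(frames=frames, frame_rate_hz=spec.frame_rate_hz,
                  stimulus_frame=spec.stimulus_frame, pixel_pitch_mm=spec.pixel_pitch_mm)
    truth = MovieTruth(
        spec=spec, slice_scale=slice_scale,
        dff_peak_by_region={name: float(spec.epsp_amplitude * slice_scale
                                        * spec.region_amp_scale.get(name, 1.0))
                            for name in REGION_ORDER},
        wave_velocity_m_per_s=spec.wave_velocity_m_per_s,
    )
    return movie, truth


def make_raster(spec: SynthSpec, width_mm: float = 0.1, seed: int = None):
    """One slice through the full pipeline: (raster, geometry, assignment, truth)."""
    outline = make_geometry(spec)
    geometry = build_segment_polygons(outline, width_mm)
    movie, truth = make_movie(spec, outline, seed=seed)
    assignment = assign_pixels(geometry, movie.frame_shape, spec.pixel_pitch_mm)
    raster = build_raster(movie, geometry, assignment)
    return raster, geometry, assignment, truth


@dataclass(frozen=True)
class RasterGroups:
    """Two groups of standardized rasters plus the ground-truth effect location."""

    group_a: tuple
    group_b: tuple
    grid: StandardGrid
    effect_regions: tuple      # regions where the specs' amplitude scale differs

    def effect_mask(self) -> np.ndarray:
        """Boolean (rows, frames) mask: effect rows x post-stimulus frames."""
        ref = self.group_a[0]
        mask = np.zeros(ref.values.shape, dtype=bool)
        post = ref.time_ms > 0
        for region in self.effect_regions:
            start, stop = self.grid.region_spans[region]
            mask[start:stop, post] = True
        return mask


def make_raster_groups(spec_a: SynthSpec, spec_b: SynthSpec, n_per_group: int,
                       seed: int = 0, width_mm: float = 0.1,
                       grid: StandardGrid = None) -> RasterGroups:
    """Generate two groups of independent slices through the full pipeline.

    Identical specs yield exchangeable groups (the null-calibration input);
    a spec_b with a scaled regional EPSP amplitude yields a known effect
    location.  Per-slice randomness is derived from ``seed``.
    """
    grid = grid or StandardGrid()
    child = iter(np.random.SeedSequence(seed).generate_state(2 * n_per_group) % (2 ** 31))

    def build_group(spec):
        outline = make_geometry(spec)
        geometry = build_segment_polygons(outline, width_mm)
        rasters, assignment = [], None
        for _ in range(n_per_group):
            movie, _ = make_movie(spec, outline, seed=int(next(child)))
            if assignment is None:   # frame shape is spec-determined; reuse
                assignment = assign_pixels(geometry, movie.frame_shape, spec.pixel_pitch_mm)
            rasters.append(standardize_raster(
                build_raster(movie, geometry, assignment), grid))
        return tuple(rasters)

    group_a = build_group(spec_a)
    group_b = build_group(spec_b)
    effect = tuple(r for r in REGION_ORDER
                   if spec_a.region_amp_scale.get(r, 1.0) != spec_b.region_amp_scale.get(r, 1.0))
    return RasterGroups(group_a=group_a, group_b=group_b, grid=grid,
                        effect_regions=effect)


def null_spec(seed: int = 0, **overrides) -> SynthSpec:
    """Study-condition control spec (no effect, no wave)."""
    return replace(SynthSpec(seed=seed), **overrides)


def effect_spec(seed: int = 0, ca1_scale: float = 0.5, **overrides) -> SynthSpec:
    """Spec with a depressed CA1 EPSP amplitude (the known group difference)."""
    return replace(SynthSpec(seed=seed, region_amp_scale={"CA1": ca1_scale}), **overrides)
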