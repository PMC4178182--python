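# Methods

This note records the analysis model implemented by `vsdikit`, the default
parameters and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that affect results.

## 1. Analysis model

### 1.1 Anatomy-guided segmentation (`geometry`)

Input is a hand-drawn slice outline: a midline polyline through the pyramidal
cell layer, two boundary polylines on either side of the lamina, and arc
positions (mm) of the region transitions hilus → CA3 → CA1.

1. **Midline smoothing.** The drawn midline is smoothed with a symmetric
   moving average (default window 99 points). Hand-drawn polylines are dense
   (vertex spacing ~2 µm) and jittery; without smoothing, local normals swing
   wildly and radial lines cross. At the polyline ends the window shrinks
   symmetrically so the endpoints are fixed points of the filter.
2. **Fixed-arc-width partition.** The smoothed midline is cut at fixed arc
   intervals (default 0.1 mm) starting at the first transition mark. A
   partial tail shorter than half a width is merged into the last full
   segment rather than kept as a sliver, so segment areas stay comparable.
3. **Radial lines and polygons.** At each cut the local normal (central-
   difference tangent rotated 90°, oriented toward the chosen boundary) is
   intersected with the boundary polyline; the first intersection along the
   ray is used. Each segment polygon is closed by the midline arc and the
   boundary arc between two consecutive radial lines. Drawn boundaries should
   overhang the midline ends slightly so the terminal radial lines always
   find an intersection.
4. **Region labels.** Each segment is labeled hilus/CA3/CA1 by the position
   of its mid-arc relative to the transition marks.
5. **Pixel assignment.** A pixel belongs to a segment if its center,
   `((col + 0.5)·pitch, (row + 0.5)·pitch)`, is covered by the polygon.
   Pixels on shared edges are assigned to the lower-index segment; a
   taken-mask guarantees the assignment is disjoint. Segments narrower than
   the pixel pitch can end up empty; they produce NaN raster rows and a
   warning rather than an error.

### 1.2 ΔF/F and rasters (`transform`)

ΔF/F is computed per pixel against the mean of the pre-stimulus frames, with
a sign convention option because some dyes decrease fluorescence on
depolarization. A pixel with zero baseline is reported by name rather than
silently producing infinities.

The raster value of segment *k* at frame *t* is the mean ΔF/F over the
segment's pixels, then filtered along time with a running median of 10 ms
width (5 frames at 500 Hz; the window is the nearest odd frame count and
shrinks symmetrically at the edges). The median suppresses single-frame
camera artifacts without smearing onset kinetics the way a mean filter would.
Row 0 is the hilus end of the lamina.

### 1.3 Co-alignment (`coalign`)

Slices differ in size, so rasters are stretched region by region onto a
standard grid — hilus 4, CA3 24, CA1 16 rows (44 total) — chosen to match the
typical region proportions at 0.1 mm segments so that stretching is mild.
Rows are treated as samples at the centers of equal arc fractions and
linearly interpolated; region endpoints map to region endpoints, constants
are preserved exactly, and the operation is idempotent. The time axis is
never resampled. A standardized raster is flagged and refused by
real-unit analyses (velocity, morphometry).

### 1.4 Sitewise permutation statistics (`stats`)

For two groups of standardized rasters the test statistic at each site is the
difference of group means. The null distribution reassigns whole slices to
pseudo-groups — slices, not sites, are the exchangeable units, so no
correction for the 13,244 parallel sites is needed to keep the per-site level
exact.

- **Exact mode** (default whenever the number of unique splits ≤ 1000):
  all unordered splits are enumerated; for equal group sizes, complementary
  splits are identical in |statistic|, so slice 0 is pinned to group A and
  the count is halved (10 slices 5 v 5 → 126). The p-value is the fraction of
  splits with |T| ≥ |T_observed|; the observed labeling is one of the
  enumerated splits, so p ≥ 1/n_splits and p-values live on the lattice
  k/n_splits.
- **Monte-Carlo mode** (larger designs): p = (1 + #{|T*| ≥ |T|}) / (n + 1)
  with the observed labeling included, the standard bias-safe estimator.

Thresholding keeps sites with p < α strictly; with exact 126-split
enumeration that means k ≤ 6, so under exchangeability the expected
significant-site rate is exactly 6/126 = 4.76% against the nominal 5% — the
quantity verified by `scripts/acceptance.py`. A Benjamini–Hochberg helper is
provided but not part of the default pipeline, matching the
whole-slice-permutation logic above.

**Null calibration** applies the same test to all (or a random subset of)
pseudo-group splits of a single homogeneous control group and reports the
distribution of significant-site fractions, giving an empirical
false-positive rate for any chosen α.

### 1.5 Velocity (`velocity`)

The activation time of a raster row is the time of the maximal first
derivative (central differences) of its trace inside a post-stimulus search
window; ties break to the earliest frame. Distances are cumulative
centroid-to-centroid gaps along the selected rows on the original geometry.
Velocity is the OLS slope of distance (mm) on time (ms), numerically equal to
m/s. Standardized rasters are refused: stretching rows would distort
distances.

### 1.6 Morphometry (`morphometry`)

Midline arc length and summed polygon area per slice, compared between groups
metric-by-metric with Welch's unequal-variance t-test and the percent
difference of group means.

### 1.7 SNR parity (`snr`)

Per segment, SNR = (peak ΔF/F in the EPSP window) / (RMS of the pre-stimulus
baseline). Each wedge is paired with a circular ROI centered at the wedge's
center of mass containing **exactly as many pixel centers** as the wedge (the
nearest-n discrete disk). Matching by area instead would let boundary
discretization change the pixel count — a circle of equal area typically
covers a few more or fewer pixel centers, scaling the averaged noise RMS by
√n bookkeeping and biasing the comparison for reasons unrelated to ROI shape.
The paired t-test across segments then compares spatial arrangement only.

### 1.8 Rendering (`viz`)

A diverging colormap built in HSV space: hue 0.05 (warm) for depolarization,
0.60 (cool) for hyperpolarization, saturation = |x| and value = 0.5 + 0.5|x|,
giving a mid-gray zero so spatially clustered low-amplitude activity remains
visible without noise thresholding. Rasters are rendered bottom-up (hilus at
the bottom) with 1-row white dividers between regions inserted at render time
only. Movie-frame overlays pseudocolor only pixels with |ΔF/F| > k·σ_noise
(default k = 1.5), leaving the raw grayscale anatomy elsewhere.

## 2. Synthetic generator (`synth`)

The generator exists so every analysis can be tested against known ground
truth; its defaults are the study conditions used throughout the test suite.

| Parameter | Default | Rationale |
|---|---|---|
| lamina length / regions | 3.3 mm, 0.3/1.8/1.2 mm | matches the 4/24/16 standard-grid proportions at 0.1 mm segments |
| lamina width | 0.3 mm (midline→boundary) | typical CA-field laminar depth at this scale |
| pixel pitch | 0.025 mm | standard high-speed VSDI camera resolution |
| frame rate / frames | 500 Hz, 301 frames, stimulus at 50 | 100 ms baseline + 500 ms response |
| baseline F₀ | 1000 counts, 10% lognormal pixel jitter | staining heterogeneity |
| EPSP | 3% ΔF/F, 2 ms rise / 10 ms decay | fast evoked depolarization; double-exponential envelope normalized to unit analytic peak |
| IPSP | 0.5%, 20 ms / 100 ms | slow hyperpolarization following the EPSP |
| noise | σ = 0.003 i.i.d. Gaussian per pixel/frame | shot-noise scale relative to a 3% signal |
| amplitude jitter | 10% lognormal per slice | slice-to-slice variability, the quantity the permutation test must respect |
| wave velocity | off (synchronous) | optional; onset delay = arc distance / velocity |
| effect | `region_amp_scale`, e.g. `{"CA1": 0.5}` | plants a known group difference with an exact ground-truth mask |

Every movie carries a `MovieTruth` (realized slice amplitude, per-region peak
ΔF/F, wave delay function); `make_raster_groups` returns the ground-truth
effect mask alongside the data. Boundaries are generated with a small
overhang past the midline ends, as hand-drawn outlines have.

**Scope.** The generator emulates what the *analysis* is sensitive to:
geometry, kinetics, amplitude structure, propagation, noise, and staining
heterogeneity. It does not model photobleaching, dye internalization drifts,
optical point-spread blur, spatially correlated noise, heartbeat/movement
artifacts, or nonlinear dye response — the pipeline contains no detrending
stage, so such effects must be corrected upstream.

## 3. Numerical choices

- All computation in float64; TIFF movies are stored float32 (raw counts
  ~10³, so the round-trip error is ~10⁻⁴ counts).
- Row interpolation is piecewise-linear (`scipy.interpolate.interp1d`):
  monotone, local, constant-preserving, idempotent; no ringing near sharp
  onsets, unlike spline or Fourier resampling.
- The running median uses a sliding window in the interior and symmetric
  shrinking windows at the edges, so no padding values are invented.
- Exact permutation p-values are computed by a single weight-matrix product
  over all splits and compared bit-for-bit against the observed row taken
  from the same enumeration, so self-comparison is exact and p ≥ 1/n_splits
  by construction.
- Tie-breaks are deterministic everywhere (earliest frame for activation
  times, lower index for shared-edge pixels, distance-then-row-major for
  matched circles); rerunning any analysis reproduces results exactly for a
  given seed.
- Polygon operations (containment, area, centroid, intersections) are
  delegated to shapely/GEOS rather than re-implemented.

## 4. Problem sizes and runtime

The standard design — 10 slices, 44 × 301 = 13,244 sites, 126 exhaustive
splits — runs in about 2 s on one CPU (slice synthesis plus pipeline
~0.15 s/slice; the exact test itself ~15 ms). Monte-Carlo mode with 1000
permutations is used automatically whenever `count_unique_partitions` exceeds
`exact_cap` (default 1000), e.g. for designs of 7 v 7 (1716 splits) and
larger; 6 v 6 (462 splits) is still exact.

## 5. Limitations

- Segmentation uses one boundary side at a time (the lamina between midline
  and the chosen boundary); analyzing both banks requires two passes.
- The permutation test assumes whole-slice exchangeability under the null;
  systematic batch effects between groups (different days, dyes, cameras)
  violate it and are not detectable from within the test.
- Exact enumeration is capped (default 1000 splits); larger designs get
  Monte-Carlo p-values with seed-controlled reproducibility.
- Velocity fitting assumes a single monotone wavefront within the search
  window; re-entrant or colliding waves need windowed re-analysis.
- The standard grid's row counts (4/24/16) are a convention: rasters with
  more rows per region than the grid are down-sampled with a warning.
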