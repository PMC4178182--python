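"""Sitewise two-group permutation testing on standardized rasters.

The exchangeable unit is the whole slice: a permutation reassigns entire
rasters to pseudo-groups, which preserves the spatial and temporal
correlation structure within each slice.  At every (row, frame) site the test
statistic is the difference of group means, and the two-sided p-value is the
fraction of label permutations (the observed labeling included) whose
absolute statistic is at least the observed one.  With equal group sizes the
label swap maps a split onto itself, so exact enumeration runs over unordered
splits — 126 of them for two groups of 5 — and exact p-values live on the
1/126 lattice.

No multiple-comparisons correction is applied by default: neighbouring sites
are strongly correlated, so instead the expected chance rate of positive
sites is calibrated directly by splitting a homogeneous control group into
pseudo-groups (:func:`null_calibration`).  An optional Benjamini-Hochberg
adjustment is available for users who want it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError
from .transform import Raster

DEFAULT_ALPHA = 0.05
DEFAULT_N_MONTE_CARLO = 1000
DEFAULT_EXACT_CAP = 1000


@dataclass(frozen=True)
class SiteMap:
    """Per-site p-values and group differences on the standard raster grid."""

    p_values: np.ndarray         # (rows, frames) in [0, 1]
    diff: np.ndarray             # mean(group B) - mean(group A), per site
    alpha: float
    n_perms_used: int
    exact: bool
    region_spans: dict = None
    time_ms: np.ndarray = None

    def __post_init__(self):
        if self.p_values.shape != self.diff.shape:
            raise InvalidParameterError("p_values and diff must have the same shape")
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must lie in (0, 1)")

    @property
    def significant_mask(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def n_sites(self) -> int:
        return self.p_values.size

    @property
    def significant_fraction(self) -> float:
        return float(self.significant_mask.mean())


@dataclass(frozen=True)
class ThresholdedMap:
    """Difference map masked to significant sites, with the counts captions report."""

    values: np.ndarray           # diff where significant, NaN elsewhere
    n_significant: int
    n_sites: int

    @property
    def fraction(self) -> float:
        return self.n_significant / self.n_sites


def count_unique_partitions(n_total: int, n_group_a: int) -> int:
    """Distinct unordered splits of n_total items into groups of n_group_a and the rest.

    When the two groups have equal size, swapping the group labels yields the
    same split, so the binomial count is halved.
    """
    if not 0 < n_group_a < n_total:
        raise InvalidParameterError("need 0 < n_group_a < n_total")
    c = comb(n_total, n_group_a)
    return c // 2 if 2 * n_group_a == n_total else c


def _stack_groups(group_a, group_b):
    ga = [r.values if isinstance(r, Raster) else np.asarray(r, dtype=float) for r in group_a]
    gb = [r.values if isinstance(r, Raster) else np.asarray(r, dtype=float) for r in group_b]
    if len(ga) < 2 or len(gb) < 2:
        raise InvalidParameterError("each group needs at least 2 rasters")
    shape = ga[0].shape
    for r in ga + gb:
        if r.shape != shape:
            raise InvalidParameterError("all rasters must share one standardized shape")
    return np.stack(ga + gb), len(ga), len(gb), shape


def _weight_row(a_idx, n, n_a, n_b):
    w = np.full(n, 1.0 / n_b)
    w[list(a_idx)] = -1.0 / n_a
    return w


def _exact_weights(n: int, n_a: int, n_b: int) -> tuple:
    """Weight matrix over all unique unordered splits, and the row index of the
    observed labeling (group A = slices 0..n_a-1)."""
    if n_a == n_b:
        # pin item 0 to group A: one representative per unordered split
        combos = [(0,) + c for c in combinations(range(1, n), n_a - 1)]
    else:
        combos = list(combinations(range(n), n_a))
    observed = tuple(range(n_a))
    if observed in combos:
        obs_row = combos.index(observed)
    else:  # equal sizes with slice 0 observed in group B: the complement is listed
        complement = tuple(i for i in range(n) if i not in observed)
        obs_row = combos.index(complement)
    w = np.array([_weight_row(c, n, n_a, n_b) for c in combos])
    return w, obs_row


def permutation_test_map(group_a, group_b, alpha: float = DEFAULT_ALPHA,
                         n_monte_carlo: int = DEFAULT_N_MONTE_CARLO,
                         exact_cap: int = DEFAULT_EXACT_CAP,
                         seed: int = None) -> SiteMap:
    """Sitewise permutation test between two groups of standardized rasters.

    Uses full enumeration of unique label splits when their count is at most
    ``exact_cap`` (deterministic, seed-independent); otherwise draws
    ``n_monte_carlo`` random label permutations with the given seed and counts
    the observed labeling among them, so p is never zero.
    """
    X, n_a, n_b, shape = _stack_groups(group_a, group_b)
    n = n_a + n_b
    flat = X.reshape(n, -1)
    n_unique = count_unique_partitions(n, n_a)
    exact = n_unique <= exact_cap

    if exact:
        W, obs_row = _exact_weights(n, n_a, n_b)
        T = W @ flat
        t_obs_mag = np.abs(T[obs_row])
        p = np.mean(np.abs(T) >= t_obs_mag, axis=0)
        n_perms = n_unique
    else:
        if n_monte_carlo < 100:
            warnings.warn("n_monte_carlo < 100 gives a very coarse p lattice", stacklevel=2)
        rng = np.random.default_rng(seed)
        w_obs = _weight_row(range(n_a), n, n_a, n_b)
        rows = [w_obs]
        for _ in range(n_monte_carlo):
            rows.append(_weight_row(rng.permutation(n)[:n_a], n, n_a, n_b))
        T = np.array(rows) @ flat
        t_obs_mag = np.abs(T[0])
        p = np.sum(np.abs(T) >= t_obs_mag, axis=0) / (n_monte_carlo + 1)
        n_perms = n_monte_carlo + 1

    diff = flat[n_a:].mean(axis=0) - flat[:n_a].mean(axis=0)
    ref = group_b[0] if isinstance(group_b[0], Raster) else None
    return SiteMap(
        p_values=p.reshape(shape), diff=diff.reshape(shape), alpha=alpha,
        n_perms_used=n_perms, exact=exact,
        region_spans=dict(ref.region_spans) if ref is not None else None,
        time_ms=ref.time_ms if ref is not None else None,
    )


def threshold_difference_map(sitemap: SiteMap) -> ThresholdedMap:
    """Mask the difference map to sites with p strictly below alpha."""
    mask = sitemap.significant_mask
    values = np.where(mask, sitemap.diff, np.nan)
    return ThresholdedMap(values=values, n_significant=int(mask.sum()),
                          n_sites=sitemap.n_sites)


def benjamini_hochberg(p_values: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Optional BH step-up significance mask over all sites (off by default)."""
    p = np.asarray(p_values, dtype=float).ravel()
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        mask[order[:k + 1]] = True
    return mask.reshape(np.shape(p_values))


@dataclass(frozen=True)
class NullCalibration:
    """Distribution of positive-site fractions across pseudo-group splits."""

    fractions: np.ndarray
    alpha: float
    exhaustive: bool

    @property
    def mean_fraction(self) -> float:
        return float(self.fractions.mean())

    def ecdf(self):
        """Empirical CDF: (sorted fractions, cumulative probabilities)."""
        x = np.sort(self.fractions)
        return x, np.arange(1, len(x) + 1) / len(x)


def null_calibration(control_rasters, n_splits: int = DEFAULT_N_MONTE_CARLO,
                     alpha: float = DEFAULT_ALPHA, seed: int = None) -> NullCalibration:
    """False-positive rate of the sitewise test under a homogeneous null.

    Control slices are repeatedly split into two pseudo-groups; each split is
    tested and the fraction of sites with p < alpha recorded.  All unique
    splits are visited when there are at most ``n_splits`` of them, otherwise
    ``n_splits`` random splits are drawn.  For exchangeable controls the mean
    fraction should sit near alpha (on the exact-p lattice, at the largest
    attainable level not exceeding alpha).
    """
    rasters = list(control_rasters)
    n = len(rasters)
    if n < 4:
        raise InvalidParameterError("null calibration needs at least 4 control rasters")
    if not 0 <= alpha < 1:
        raise InvalidParameterError("alpha must lie in [0, 1)")
    n_a = n // 2
    total = count_unique_partitions(n, n_a)
    rng = np.random.default_rng(seed)
    if total <= n_splits:
        if n_a == n - n_a:
            splits = [(0,) + c for c in combinations(range(1, n), n_a - 1)]
        else:
            splits = list(combinations(range(n), n_a))
        exhaustive = True
    else:
        splits = [tuple(rng.permutation(n)[:n_a]) for _ in range(n_splits)]
        exhaustive = False

    fractions = np.empty(len(splits))
    for i, a_idx in enumerate(splits):
        a_set = set(a_idx)
        ga = [rasters[j] for j in sorted(a_set)]
        gb = [rasters[j] for j in range(n) if j not in a_set]
        sm = permutation_test_map(ga, gb, alpha=alpha if alpha > 0 else DEFAULT_ALPHA,
                                  seed=seed)
        fractions[i] = float((sm.p_values < alpha).mean())
    return NullCalibration(fractions=fractions, alpha=alpha, exhaustive=exhaustive)


@dataclass(frozen=True)
class ROITestResult:
    """Conventional ROI comparison: one scalar per slice, Welch t-test between groups."""

    p_value: float
    t_statistic: float
    mean_a: float
    mean_b: float
    per_slice_a: np.ndarray
    per_slice_b: np.ndarray
    degenerate: bool = False


def roi_ttest(group_a, group_b, row_range, frame_range) -> ROITestResult:
    """Average dF/F over a spatial x temporal ROI box per slice, then Welch t-test.

    This is the conventional region-of-interest analysis the sitewise map is
    compared against: it collapses each slice to one scalar before testing.
    """
    rows = np.arange(*row_range) if isinstance(row_range, tuple) else np.asarray(row_range)
    frames = np.arange(*frame_range) if isinstance(frame_range, tuple) else np.asarray(frame_range)
    if rows.size == 0 or frames.size == 0:
        raise InvalidParameterError("ROI box is empty")

    def roi_means(group):
        vals = []
        for r in group:
            v = r.values if isinstance(r, Raster) else np.asarray(r, dtype=float)
            vals.append(v[np.ix_(rows, frames)].mean())
        return np.asarray(vals)

    a, b = roi_means(group_a), roi_means(group_b)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each group needs at least 2 slices")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = np.isclose(a.mean(), b.mean())
        return ROITestResult(p_value=1.0 if equal else 0.0,
                             t_statistic=0.0 if equal else np.inf,
                             mean_a=float(a.mean()), mean_b=float(b.mean()),
                             per_slice_a=a, per_slice_b=b, degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return ROITestResult(p_value=float(p), t_statistic=float(t),
                         mean_a=float(a.mean()), mean_b=float(b.mean()),
                         per_slice_a=a, per_slice_b=b)
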