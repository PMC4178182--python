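from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_test_raster
from vsdikit.errors import InvalidParameterError
from vsdikit.stats import (SiteMap, count_unique_partitions, null_calibration,
                           permutation_test_map, roi_ttest,
                           threshold_difference_map)

SPANS = {"hilus": (0, 1), "CA3": (1, 2), "CA1": (2, 3)}


def rasters_from(arrays):
    return [make_test_raster(a, spans=SPANS) for a in arrays]


def brute_force_exact_pvalues(group_a, group_b):
    """Independent oracle: enumerate every unordered split naively."""
    data = np.array([np.asarray(g, dtype=float) for g in list(group_a) + list(group_b)])
    n, n_a = len(data), len(group_a)
    splits = []
    seen = set()
    for combo in combinations(range(n), n_a):
        rest = tuple(i for i in range(n) if i not in combo)
        key = frozenset([combo, rest]) if n_a == n - n_a else combo
        if key in seen:
            continue
        seen.add(key)
        splits.append(combo)
    t_obs = np.abs(data[n_a:].mean(axis=0) - data[:n_a].mean(axis=0))
    count = np.zeros(data.shape[1:])
    for combo in splits:
        rest = [i for i in range(n) if i not in combo]
        t = np.abs(data[rest].mean(axis=0) - data[list(combo)].mean(axis=0))
        count += (t >= t_obs)
    return count / len(splits)


class TestCountUniquePartitions:
    def test_ten_choose_five_unordered(self):
        assert count_unique_partitions(10, 5) == 126

    def test_four_choose_two_unordered(self):
        assert count_unique_partitions(4, 2) == 3

    def test_six_choose_three_matches_enumeration(self):
        seen = set()
        for combo in combinations(range(6), 3):
            rest = frozenset(set(range(6)) - set(combo))
            seen.add(frozenset([frozenset(combo), rest]))
        assert count_unique_partitions(6, 3) == len(seen) == 10

    def test_unequal_sizes_not_halved(self):
        assert count_unique_partitions(7, 3) == 35

    def test_invalid_sizes_rejected(self):
        with pytest.raises(InvalidParameterError):
            count_unique_partitions(5, 0)
        with pytest.raises(InvalidParameterError):
            count_unique_partitions(5, 5)


class TestPermutationTestMap:
    def test_identical_constant_groups_give_p_one(self):
        groups = rasters_from([np.full((3, 4), 1.0) for _ in range(4)])
        sm = permutation_test_map(groups[:2], groups[2:])
        np.testing.assert_array_equal(sm.p_values, 1.0)
        np.testing.assert_array_equal(sm.diff, 0.0)

    def test_three_v_three_minimum_p_is_one_tenth(self):
        ga = rasters_from([np.zeros((3, 1))] * 3)
        gb = rasters_from([np.ones((3, 1))] * 3)
        sm = permutation_test_map(ga, gb)
        assert sm.exact and sm.n_perms_used == 10
        np.testing.assert_allclose(sm.p_values, 0.1)
        np.testing.assert_allclose(sm.diff, 1.0)

    @pytest.mark.parametrize("n_a,n_b", [(3, 3), (4, 4), (5, 5), (3, 4)])
    def test_exact_pvalues_match_bruteforce_oracle(self, rng, n_a, n_b):
        ga = [rng.normal(size=(3, 4)) for _ in range(n_a)]
        gb = [rng.normal(size=(3, 4)) for _ in range(n_b)]
        sm = permutation_test_map(rasters_from(ga), rasters_from(gb))
        assert sm.exact
        np.testing.assert_array_equal(sm.p_values, brute_force_exact_pvalues(ga, gb))

    def test_exact_p_on_lattice_and_bounded_below(self, rng):
        ga = rasters_from([rng.normal(size=(3, 3)) for _ in range(4)])
        gb = rasters_from([rng.normal(size=(3, 3)) for _ in range(4)])
        sm = permutation_test_map(ga, gb)
        counts = sm.p_values * sm.n_perms_used
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert sm.p_values.min() >= 1.0 / sm.n_perms_used

    def test_monte_carlo_reproducible_and_converges_to_exact(self, rng):
        ga = [rng.normal(size=(3, 2)) for _ in range(4)]
        gb = [rng.normal(size=(3, 2)) for _ in range(4)]
        exact = permutation_test_map(rasters_from(ga), rasters_from(gb))
        n_mc = 4000
        mc1 = permutation_test_map(rasters_from(ga), rasters_from(gb),
                                   exact_cap=1, n_monte_carlo=n_mc, seed=7)
        mc2 = permutation_test_map(rasters_from(ga), rasters_from(gb),
                                   exact_cap=1, n_monte_carlo=n_mc, seed=7)
        np.testing.assert_array_equal(mc1.p_values, mc2.p_values)
        assert not mc1.exact
        se = np.sqrt(exact.p_values * (1 - exact.p_values) / n_mc)
        assert np.all(np.abs(mc1.p_values - exact.p_values) <= 3 * se + 1.0 / n_mc)

    def test_label_swap_negates_diff_and_keeps_p(self, rng):
        ga = rasters_from([rng.normal(size=(3, 3)) for _ in range(3)])
        gb = rasters_from([rng.normal(size=(3, 3)) for _ in range(3)])
        fwd = permutation_test_map(ga, gb)
        rev = permutation_test_map(gb, ga)
        np.testing.assert_allclose(rev.diff, -fwd.diff, atol=1e-15)
        np.testing.assert_array_equal(rev.p_values, fwd.p_values)

    def test_group_of_one_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            permutation_test_map(rasters_from([rng.normal(size=(3, 2))]),
                                 rasters_from([rng.normal(size=(3, 2))] * 3))


class TestThresholdDifferenceMap:
    def _sitemap(self, p, diff, alpha=0.05):
        return SiteMap(p_values=p, diff=diff, alpha=alpha, n_perms_used=126, exact=True)

    def test_all_p_one_fully_masked(self):
        out = threshold_difference_map(self._sitemap(np.ones((4, 5)), np.ones((4, 5))))
        assert out.n_significant == 0 and out.fraction == 0.0
        assert np.isnan(out.values).all()

    def test_counts_sites_below_alpha(self):
        p = np.ones((4, 5))
        p[0, :3] = 0.01
        out = threshold_difference_map(self._sitemap(p, np.full((4, 5), 2.0)))
        assert out.n_significant == 3
        assert out.fraction == 3 / 20
        assert np.nansum(out.values) == 6.0

    def test_p_equal_alpha_is_masked(self):
        p = np.full((2, 2), 0.05)
        out = threshold_difference_map(self._sitemap(p, np.ones((2, 2))))
        assert out.n_significant == 0


class TestNullCalibration:
    def test_ten_controls_give_126_fractions(self, rng):
        controls = rasters_from([rng.normal(size=(3, 3)) for _ in range(10)])
        cal = null_calibration(controls, n_splits=1000, alpha=0.05, seed=0)
        assert cal.exhaustive
        assert len(cal.fractions) == 126

    def test_alpha_zero_gives_zero_fractions(self, rng):
        controls = rasters_from([rng.normal(size=(3, 3)) for _ in range(6)])
        cal = null_calibration(controls, alpha=0.0, seed=0)
        np.testing.assert_array_equal(cal.fractions, 0.0)

    def test_exchangeable_controls_mean_rate_on_exact_lattice(self, rng):
        # with 8 controls split 4v4 (35 splits), p<0.05 means p <= 1/35,
        # so the expected positive rate is exactly 1/35 under exchangeability
        controls = rasters_from([rng.normal(size=(3, 50)) for _ in range(8)])
        cal = null_calibration(controls, n_splits=100, alpha=0.05, seed=0)
        assert abs(cal.mean_fraction - 1 / 35) < 0.01

    def test_ecdf_is_monotone(self, rng):
        controls = rasters_from([rng.normal(size=(3, 3)) for _ in range(6)])
        cal = null_calibration(controls, alpha=0.05, seed=0)
        x, f = cal.ecdf()
        assert np.all(np.diff(x) >= 0) and f[-1] == 1.0

    def test_too_few_controls_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            null_calibration(rasters_from([rng.normal(size=(3, 2))] * 3))


class TestRoiTTest:
    def test_identical_groups_p_one(self):
        groups = rasters_from([np.full((3, 4), 2.0)] * 4)
        res = roi_ttest(groups[:2], groups[2:], (0, 3), (0, 4))
        assert res.p_value == 1.0 and res.degenerate

    def test_zero_variance_different_means_flagged(self):
        ga = rasters_from([np.zeros((3, 4))] * 2)
        gb = rasters_from([np.ones((3, 4))] * 2)
        res = roi_ttest(ga, gb, (0, 3), (0, 4))
        assert res.p_value == 0.0 and res.degenerate

    def test_matches_welch_closed_form(self, rng):
        ga = [rng.normal(size=(3, 4)) for _ in range(5)]
        gb = [rng.normal(loc=0.5, size=(3, 4)) for _ in range(4)]
        res = roi_ttest(rasters_from(ga), rasters_from(gb), (1, 3), (0, 2))
        a = np.array([g[1:3, 0:2].mean() for g in ga])
        b = np.array([g[1:3, 0:2].mean() for g in gb])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert abs(res.t_statistic - t) < 1e-10
        assert abs(res.p_value - p) < 1e-10

    def test_empty_roi_rejected(self, rng):
        groups = rasters_from([rng.normal(size=(3, 4)) for _ in range(4)])
        with pytest.raises(InvalidParameterError):
            roi_ttest(groups[:2], groups[2:], (1, 1), (0, 4))
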