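import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lgnbinoc import binocular_stats as bs


class TestPercentModulation:
    @pytest.mark.parametrize("mono,binoc,expected", [
        (10.0, 10.0, 0.0),
        (10.0, 9.0, -10.0),
        (10.0, 11.5, 15.0),
    ])
    def test_examples(self, mono, binoc, expected):
        assert bs.percent_modulation(mono, binoc) == pytest.approx(expected)

    def test_nonpositive_mono_rejected(self):
        with pytest.raises(ValueError):
            bs.percent_modulation(0.0, 5.0)


class TestMadOutlierFilter:
    def test_gross_outlier_excluded(self):
        mask = bs.mad_outlier_filter([0.0, 0.0, 0.0, 0.0, 100.0])
        assert mask.tolist() == [True, True, True, True, False]

    def test_normal_sample_exclusion_fraction(self):
        # the 3-scaled-MAD rule on a Normal sample excludes ~2*Phi(-3)=0.27%
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        frac = 1.0 - bs.mad_outlier_filter(x).mean()
        assert frac == pytest.approx(0.0027, abs=0.0025)

    def test_identical_values_all_retained(self):
        assert bs.mad_outlier_filter([5.0] * 6).all()

    @given(st.lists(st.integers(-100, 100), min_size=3, max_size=40),
           st.sampled_from([0.5, 2.0, 16.0]), st.integers(-50, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_affine_invariance(self, xs, scale, shift):
        xs = np.asarray(xs, dtype=float)
        m1 = bs.mad_outlier_filter(xs)
        m2 = bs.mad_outlier_filter(scale * xs + shift)
        assert (m1 == m2).all()


class TestPopulationTest:
    def test_symmetric_values_give_p_near_one(self):
        x = np.array([1.0, -1.0, 2.5, -2.5, 4.0, -4.0, 5.5, -5.5])
        s = bs.population_test(x, rng=np.random.default_rng(0))
        assert s.wilcoxon_p > 0.95
        assert s.median_percent_diff == 0.0

    def test_one_sided_mass_gives_smallest_attainable_p(self):
        x = np.full(10, -5.0)
        s = bs.population_test(x, rng=np.random.default_rng(0))
        assert s.median_percent_diff == -5.0
        assert s.wilcoxon_p < 0.01

    def test_ci_contains_median(self):
        rng = np.random.default_rng(1)
        x = rng.normal(-10, 5, size=40)
        s = bs.population_test(x, rng=rng)
        assert s.ci_low <= s.median_percent_diff <= s.ci_high

    def test_small_sample_flagged_undefined(self):
        s = bs.population_test([1.0, 2.0], rng=np.random.default_rng(0))
        assert s.wilcoxon_p is None

    def test_detects_shifted_population(self):
        # power check: 56 units, true median -10, unit-level SD 10
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(50):
            x = rng.normal(-10, 10, size=56)
            s = bs.population_test(x, n_boot=200, rng=rng)
            rejections += s.wilcoxon_p < 0.05
        assert rejections / 50 >= 0.8


class TestRocAuc:
    def brute_force(self, b, m):
        wins = sum(x > y for x, y in itertools.product(b, m))
        ties = sum(x == y for x, y in itertools.product(b, m))
        return (wins + 0.5 * ties) / (len(b) * len(m))

    def test_identical_samples_give_half(self):
        assert bs.roc_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_fully_separated_samples_give_one(self):
        assert bs.roc_auc([4, 5, 6], [1, 2, 3]) == 1.0

    def test_overlapping_integer_example(self):
        # all 9 pairs: 6 wins + 2 ties -> (6 + 1)/9
        assert bs.roc_auc([2, 3, 4], [1, 2, 3]) == pytest.approx(7 / 9)

    @given(st.lists(st.integers(0, 9), min_size=1, max_size=8),
           st.lists(st.integers(0, 9), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rank_formula_equals_pair_enumeration(self, b, m):
        assert bs.roc_auc(b, m) == pytest.approx(self.brute_force(b, m))


class TestShuffleNull:
    def test_separated_samples_significant_with_direction(self):
        rng = np.random.default_rng(0)
        r = bs.shuffle_null(np.arange(20, 40), np.arange(0, 20), rng=rng)
        assert r.significant and r.direction == "facilitation"
        r2 = bs.shuffle_null(np.arange(0, 20), np.arange(20, 40),
                             rng=np.random.default_rng(0))
        assert r2.significant and r2.direction == "suppression"

    def test_same_seed_same_result(self):
        rng_data = np.random.default_rng(1)
        b = rng_data.normal(size=15)
        m = rng_data.normal(size=15)
        r1 = bs.shuffle_null(b, m, rng=np.random.default_rng(7))
        r2 = bs.shuffle_null(b, m, rng=np.random.default_rng(7))
        assert r1 == r2

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError):
            bs.shuffle_null([1, 2], [3, 4], n_shuffles=10)

    def test_label_permutation_also_calibrated_on_separated_input(self):
        r = bs.shuffle_null(np.arange(20, 40), np.arange(0, 20),
                            rng=np.random.default_rng(2),
                            method="label_permutation")
        assert r.significant


class TestProportionTrend:
    def test_equal_proportions_give_zero_slope(self):
        slope, p, df = bs.proportion_trend([20.0, 20.0, 20.0], [0.12, 0.34, 0.9])
        assert slope == pytest.approx(0.0)
        assert df == 1

    def test_exactly_linear_data_recovers_coefficient(self):
        x = np.array([0.12, 0.34, 0.9, 0.95])
        y = 30.0 - 12.0 * x
        slope, p, df = bs.proportion_trend(y, x)
        assert slope == pytest.approx(-12.0)
        assert p < 1e-6

    def test_three_point_slope_matches_closed_form(self):
        x = np.array([0.12, 0.34, 0.9])
        y = np.array([25.0, 15.0, 10.0])
        slope, p, df = bs.proportion_trend(y, x)
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / ((x - x.mean()) ** 2).sum())
        assert slope == pytest.approx(expected)
        assert df == 1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            bs.proportion_trend([10.0, 20.0], [0.1, 0.9])


class TestCrfAverage:
    def test_single_unit_equals_its_normalized_curve(self):
        grid, out = bs.crf_average({"u0": {0.12: 2.0, 0.34: 6.0, 0.9: 10.0}})
        np.testing.assert_allclose(out["mean"], [0.0, 0.5, 1.0])

    def test_max_bin_pinned_at_one_when_shared(self):
        units = {f"u{i}": {0.12: v, 0.9: 10.0 + i}
                 for i, v in enumerate([1.0, 3.0, 5.0])}
        grid, out = bs.crf_average(units)
        assert out["mean"][-1] == pytest.approx(1.0)

    def test_constant_response_unit_excluded(self):
        grid, out = bs.crf_average({"flat": {0.12: 2.0, 0.9: 2.0},
                                    "ok": {0.12: 0.0, 0.9: 1.0}})
        assert out["excluded"] == ["flat"]


def test_modulation_density_integrates_to_one():
    rng = np.random.default_rng(3)
    grid, dens = bs.modulation_density(rng.normal(size=200))
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)
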