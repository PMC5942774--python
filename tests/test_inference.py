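"""Anderson-Darling stage, dominance permutation stage, two-stage verdicts."""

import math

import numpy as np
import pytest

from cibkit.inference import (
    VERDICT_SAME,
    VERDICT_UNORDERED,
    VERDICT_X_SMALLER,
    VERDICT_Y_SMALLER,
    ad_2sample,
    compare_groups,
    dominance_test,
)

from conftest import ad_continuous_double_sum


class TestAD2Sample:
    def test_worked_continuous_statistic(self):
        r = ad_2sample([1, 2, 3], [4, 5, 6], variant="continuous")
        assert r.statistic == pytest.approx(2.4, abs=1e-12)
        oracle = ad_continuous_double_sum([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(oracle, abs=1e-12)

    def test_continuous_matches_double_sum_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(size=rng.integers(3, 12))
            r = ad_2sample(x, y, variant="continuous")
            assert r.statistic == pytest.approx(
                ad_continuous_double_sum(list(x), list(y)), abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=5)
        a = ad_2sample(x, y)
        b = ad_2sample(y, x)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_rank_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=12)
        a = ad_2sample(x, y)
        b = ad_2sample(np.exp(x), np.exp(y))  # strictly increasing transform
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_identical_multisets_permutation_p_is_one(self):
        r = ad_2sample([1, 2, 2, 3], [3, 2, 2, 1], method="permutation",
                       n_permutations=500, seed=0)
        assert r.p_value == pytest.approx(1.0)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ad_2sample([1], [1, 2])

    def test_p_value_in_unit_interval(self):
        rng = np.random.default_rng(5)
        r = ad_2sample(rng.normal(size=30), rng.normal(size=30) + 3)
        assert 0.0 <= r.p_value <= 1.0
        assert r.p_value <= 0.01  # clearly separated samples


class TestDominance:
    def test_fully_separated_exhaustive(self):
        r = dominance_test([1, 2, 3], [101, 102, 103], "x_below_y")
        assert r.exhaustive
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1 / 20)

    def test_identical_constants(self):
        for direction in ("x_below_y", "y_below_x"):
            r = dominance_test([5, 5, 5], [5, 5, 5], direction)
            assert r.statistic == 0.0
            assert r.p_value == pytest.approx(1.0)

    def test_unknown_direction(self):
        with pytest.raises(ValueError):
            dominance_test([1, 2], [3, 4], "sideways")

    def test_zero_permutations_rejected_for_large_samples(self):
        x = list(range(10))
        y = list(range(10, 20))
        with pytest.raises(ValueError):
            dominance_test(x, y, "x_below_y", n_permutations=0)

    def test_direction_negation_symmetry(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=9), rng.normal(size=7) + 0.5
        a = dominance_test(x, y, "x_below_y", n_permutations=10, seed=0)
        b = dominance_test(-x, -y, "y_below_x", n_permutations=10, seed=0)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_monte_carlo_matches_exhaustive(self):
        # pooled n = 10 -> exhaustive; force MC by lowering the threshold
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=5), rng.normal(size=5) + 1.0
        exact = dominance_test(x, y, "x_below_y")
        assert exact.exhaustive
        mc = dominance_test(x, y, "x_below_y", n_permutations=100_000,
                            seed=1, exhaustive_max_n=0)
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 100_000)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 2 / 100_000

    def test_p_never_zero_in_monte_carlo(self):
        x = list(range(20))
        y = list(range(100, 120))
        r = dominance_test(x, y, "x_below_y", n_permutations=200, seed=0)
        assert r.p_value >= 1 / 201

    def test_rank_invariance(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=15), rng.normal(size=15) + 1
        a = dominance_test(x, y, "x_below_y", n_permutations=50, seed=3)
        b = dominance_test(np.exp(x), np.exp(y), "x_below_y",
                           n_permutations=50, seed=3)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p_value == b.p_value


class TestCompareGroups:
    def test_separated_groups_ordered_verdict(self):
        rng = np.random.default_rng(0)
        cib_x = {c: rng.uniform(0.0, 0.2, 40) for c in "POC"}
        cib_y = {c: rng.uniform(0.5, 0.8, 40) for c in "POC"}
        results = compare_groups(cib_x, cib_y, alpha=0.01,
                                 n_permutations=1000, seed=1)
        assert len(results) == 3
        assert all(r.verdict == VERDICT_X_SMALLER for r in results)
        swapped = compare_groups(cib_y, cib_x, alpha=0.01,
                                 n_permutations=1000, seed=1)
        assert all(r.verdict == VERDICT_Y_SMALLER for r in swapped)

    def test_identical_groups_same_verdict(self):
        rng = np.random.default_rng(1)
        sample = {c: rng.normal(size=30) for c in "AB"}
        results = compare_groups(sample, sample, alpha=0.01,
                                 n_permutations=200, seed=2)
        assert all(r.verdict == VERDICT_SAME for r in results)
        assert all(r.dom_xy is None and r.dom_yx is None for r in results)

    def test_small_category_skipped(self):
        rng = np.random.default_rng(2)
        cib_x = {"P": rng.normal(size=10), "Q": [0.1]}
        cib_y = {"P": rng.normal(size=10), "Q": [0.2, 0.3]}
        results = compare_groups(cib_x, cib_y, seed=0, n_permutations=100)
        assert [r.category for r in results] == ["P"]

    def test_nan_rows_dropped(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.uniform(0, 0.2, 20), [np.nan, np.nan]])
        y = rng.uniform(0.5, 0.8, 20)
        results = compare_groups({"P": x}, {"P": y}, n_permutations=500, seed=4)
        assert results[0].n_x == 20

    def test_no_shared_categories(self):
        with pytest.raises(ValueError):
            compare_groups({"P": [1, 2]}, {"Q": [1, 2]})

    def test_crossing_distributions_unordered(self):
        # same mean, very different spread: AD rejects, neither dominates
        rng = np.random.default_rng(5)
        x = rng.normal(0.5, 0.01, 150)
        y = np.concatenate([rng.normal(0.2, 0.01, 75), rng.normal(0.8, 0.01, 75)])
        results = compare_groups({"P": x}, {"P": y}, alpha=0.01,
                                 n_permutations=2000, seed=6)
        assert results[0].verdict == VERDICT_UNORDERED

    def test_type_one_error_near_alpha(self):
        """Identical continuous distributions: stage-one rejects ~ alpha."""
        rng = np.random.default_rng(42)
        alpha = 0.05
        n_rep = 200
        rejections = 0
        for _ in range(n_rep):
            r = ad_2sample(rng.normal(size=40), rng.normal(size=40))
            rejections += r.p_value <= alpha
        rate = rejections / n_rep
        tol = 3 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= tol

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(7)
        rates = []
        for delta in (0.0, 0.5, 1.5):
            rej = sum(
                ad_2sample(rng.normal(size=25),
                           rng.normal(size=25) + delta).p_value <= 0.05
                for _ in range(60)
            )
            rates.append(rej / 60)
        assert rates[0] <= rates[1] + 0.1  # non-strict, simulation noise
        assert rates[2] >= rates[0]
        assert rates[2] > 0.9
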