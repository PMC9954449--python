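import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from onest.core import (
    ONEST,
    OnestResult,
    compute_opa,
    count_permutations,
    exact_extrema,
    onest_value,
    opac_for_permutation,
    prefix_opa_curves,
    run_onest,
    sample_permutations,
    summarize_curves,
)
from conftest import random_categorical


class TestComputeOpa:
    def test_perfect_agreement(self):
        cats = np.ones((7, 5), dtype=int)
        assert compute_opa(cats, range(5)) == 1.0

    def test_toy_pair(self, toy_categories):
        assert compute_opa(toy_categories, [0, 1]) == pytest.approx(0.8)

    def test_single_discordant_case(self):
        assert compute_opa(np.array([[0, 1]]), [0, 1]) == 0.0

    def test_requires_two_observers(self, toy_categories):
        with pytest.raises(ValueError, match="two observers"):
            compute_opa(toy_categories, [0])


class TestOpaCurves:
    def test_toy_identity_order(self, toy_categories):
        np.testing.assert_allclose(
            opac_for_permutation(toy_categories, [0, 1, 2, 3]), [0.8, 0.6, 0.4]
        )

    def test_identical_observers_curve_is_one(self):
        cats = np.tile(np.arange(6)[:, None] % 3, (1, 5))
        for perm in ([0, 1, 2, 3, 4], [4, 2, 0, 3, 1]):
            np.testing.assert_array_equal(opac_for_permutation(cats, perm), np.ones(4))

    def test_rejects_non_permutation(self, toy_categories):
        with pytest.raises(ValueError, match="not a permutation"):
            opac_for_permutation(toy_categories, [0, 0, 1, 2])

    @given(st.integers(0, 2**31 - 1))
    def test_curves_non_increasing_and_resolution(self, seed):
        rng = np.random.RandomState(seed)
        cats = random_categorical(rng, rng.randint(3, 15), rng.randint(3, 8))
        perms = sample_permutations(cats.shape[1], 20, rng)
        curves = prefix_opa_curves(cats, perms)
        assert (np.diff(curves, axis=1) <= 1e-12).all()
        counts = curves * cats.shape[0]
        np.testing.assert_allclose(counts, np.rint(counts), atol=1e-9)
        assert ((curves >= 0) & (curves <= 1)).all()


class TestSamplePermutations:
    def test_small_n_exhaustive(self):
        perms = sample_permutations(3, 100)
        assert perms.shape == (6, 3)
        assert len({tuple(p) for p in perms}) == 6

    def test_distinct_and_reproducible(self):
        a = sample_permutations(14, 100, random_state=11)
        b = sample_permutations(14, 100, random_state=11)
        np.testing.assert_array_equal(a, b)
        assert len({tuple(p) for p in a}) == 100

    def test_different_seeds_differ(self):
        a = sample_permutations(10, 50, random_state=0)
        b = sample_permutations(10, 50, random_state=1)
        assert not np.array_equal(a, b)

    def test_rejects_single_observer(self):
        with pytest.raises(ValueError):
            sample_permutations(1, 10)


class TestCountPermutations:
    @pytest.mark.parametrize("n, expected", [(2, 2), (9, 362_880), (14, 87_178_291_200)])
    def test_known_values(self, n, expected):
        assert count_permutations(n) == expected

    def test_large_panel_magnitude(self):
        exact = count_permutations(23)
        assert exact == math.factorial(23)
        assert f"{exact:.3e}" == "2.585e+22"


class TestSummarizeCurves:
    def test_single_curve(self):
        lo, hi, med = summarize_curves([[0.8, 0.6]])
        for c in (lo, hi, med):
            np.testing.assert_allclose(c, [0.8, 0.6])

    def test_even_count_median_is_midpoint(self):
        lo, hi, med = summarize_curves([[0.8, 0.6], [0.6, 0.6]])
        np.testing.assert_allclose(lo, [0.6, 0.6])
        np.testing.assert_allclose(hi, [0.8, 0.6])
        np.testing.assert_allclose(med, [0.7, 0.6])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_curves([])


class TestExactExtrema:
    def test_toy_pairs(self, toy_categories):
        assert exact_extrema(toy_categories, 2) == (0.6, 0.8)

    def test_full_panel_is_opa_n(self, toy_categories):
        lo, hi = exact_extrema(toy_categories, 4)
        assert lo == hi == compute_opa(toy_categories, range(4))

    def test_guard_on_huge_enumerations(self):
        cats = np.zeros((3, 30), dtype=int)
        with pytest.raises(ValueError, match="guard"):
            exact_extrema(cats, 15)

    @given(st.integers(0, 2**31 - 1))
    def test_bounds_sampled_curves(self, seed):
        rng = np.random.RandomState(seed)
        cats = random_categorical(rng, 8, 6)
        perms = sample_permutations(6, 30, rng)
        curves = prefix_opa_curves(cats, perms)
        lo, hi, _ = summarize_curves(curves)
        for k in range(2, 7):
            exact_lo, exact_hi = exact_extrema(cats, k)
            assert lo[k - 2] >= exact_lo - 1e-12
            assert hi[k - 2] <= exact_hi + 1e-12


class TestOnestValue:
    def test_constant_curve_plateaus_at_two(self):
        assert onest_value([0.7, 0.7, 0.7, 0.7], n_cases=10) == 2

    def test_worked_plateau_with_explicit_tolerance(self):
        # drop of exactly eps at k=3 blocks the plateau there
        assert onest_value([0.80, 0.70, 0.65, 0.65, 0.65], n_cases=20, tolerance=0.05) == 4

    def test_strictly_decreasing_curve_needs_full_panel(self):
        curve = [0.9 - 0.1 * i for i in range(5)]
        assert onest_value(curve, n_cases=100, tolerance=0.05) == 6

    def test_auto_tolerance_is_one_case(self):
        # 1/C = 0.1; a one-case drop is not a plateau
        assert onest_value([0.5, 0.4, 0.4], n_cases=10) == 3

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            onest_value([0.5, 0.4], n_cases=10, tolerance=0.0)


class TestRunOnest:
    def test_identical_observers(self):
        cats = np.tile(np.arange(8)[:, None] % 2, (1, 6))
        res = run_onest(cats, n_permutations=40, random_state=0)
        assert res.opa_n == 1.0
        assert res.bandwidth == 0.0
        assert res.onest_value == 2

    def test_toy_exhaustive_readings(self, toy_categories):
        res = run_onest(toy_categories, n_permutations=24, random_state=0)
        assert res.exhaustive
        assert res.opa_n == pytest.approx(0.4)
        assert res.bandwidth == pytest.approx(0.2)

    def test_deterministic_given_seed(self, toy_categories):
        a = run_onest(toy_categories, n_permutations=10, random_state=5)
        b = run_onest(toy_categories, n_permutations=10, random_state=5)
        np.testing.assert_array_equal(a.curves, b.curves)
        np.testing.assert_array_equal(a.permutations, b.permutations)
        assert a.to_dict() == b.to_dict()

    def test_summary_ordering_and_shared_endpoint(self, toy_categories):
        res = run_onest(toy_categories, n_permutations=24, random_state=1)
        assert (res.min_curve <= res.median_curve + 1e-12).all()
        assert (res.median_curve <= res.max_curve + 1e-12).all()
        assert res.min_curve[-1] == res.max_curve[-1] == res.opa_n
        np.testing.assert_allclose(res.curves[:, -1], res.opa_n)

    def test_case_relabelling_invariance(self, toy_categories):
        rng = np.random.RandomState(0)
        shuffled = toy_categories[rng.permutation(toy_categories.shape[0])]
        a = run_onest(toy_categories, n_permutations=24, random_state=2)
        b = run_onest(shuffled, n_permutations=24, random_state=2)
        np.testing.assert_allclose(a.curves, b.curves)
        assert a.onest_value == b.onest_value

    def test_exact_bandwidth_uses_all_pairs(self):
        rng = np.random.RandomState(3)
        cats = random_categorical(rng, 12, 9)
        sampled = run_onest(cats, n_permutations=20, random_state=3)
        exact = run_onest(cats, n_permutations=20, random_state=3, exact_bandwidth=True)
        lo, hi = exact_extrema(cats, 2)
        assert exact.bandwidth == pytest.approx(hi - lo)
        assert sampled.bandwidth <= exact.bandwidth + 1e-12

    def test_json_round_trip(self, tmp_path, toy_categories):
        res = run_onest(toy_categories, n_permutations=10, random_state=9)
        path = tmp_path / "result.json"
        res.to_json(path)
        back = OnestResult.from_json(path)
        assert back.to_dict() == res.to_dict()

    def test_estimator_api(self, toy_categories):
        est = ONEST(n_permutations=24, random_state=0)
        params = est.get_params()
        assert params["n_permutations"] == 24
        est.fit(pd.DataFrame(toy_categories, columns=list("wxyz")))
        assert est.result_.observer_ids == ["w", "x", "y", "z"]
        assert est.score() == est.opa_n_

    def test_duplicate_observer_cannot_lower_subset_opa(self, toy_categories):
        # appending a copy of observer 0: swapping the copy for the original
        # in any subset leaves OPA unchanged
        dup = np.hstack([toy_categories, toy_categories[:, [0]]])
        assert compute_opa(dup, [0, 4]) == 1.0
        assert compute_opa(dup, [1, 4]) == compute_opa(toy_categories, [1, 0])
        assert compute_opa(dup, [1, 2, 4]) == compute_opa(toy_categories, [1, 2, 0])
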