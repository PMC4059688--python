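"""Rank-order Wasserstein distance: oracle equivalence and metric axioms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linprog
from scipy.stats import wasserstein_distance as scipy_w1

from imfsieve import DistanceSpec, ecdf, inverse_ecdf, w_distance, windowed_w_distance


def lp_transport_cost(a, b):
    """Optimal-transport cost between two uniform empirical measures,
    solved as an explicit linear program — the independent oracle."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    A_eq = []
    for i in range(na):  # row marginals
        row = np.zeros((na, nb))
        row[i, :] = 1.0
        A_eq.append(row.ravel())
    for j in range(nb):  # column marginals
        col = np.zeros((na, nb))
        col[:, j] = 1.0
        A_eq.append(col.ravel())
    b_eq = np.concatenate([np.full(na, 1.0 / na), np.full(nb, 1.0 / nb)])
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=b_eq, bounds=(0, None),
                  method="highs")
    assert res.success
    return res.fun


class TestEcdf:
    def test_rank_count(self):
        assert ecdf([1, 2, 3], 2) == pytest.approx(2 / 3)

    def test_range_limits(self):
        s = [1.0, 2.0, 3.0]
        assert ecdf(s, 0.5) == 0.0
        assert ecdf(s, 3.0) == 1.0
        assert ecdf(s, 99.0) == 1.0

    def test_duplicates(self):
        assert ecdf([5, 5], 5) == 1.0

    def test_empty_sample(self):
        with pytest.raises(ValueError, match="nonempty"):
            ecdf([], 0.0)


class TestInverseEcdf:
    def test_median_of_three(self):
        # smallest v with ecdf(v) >= 0.5 among sorted {1,2,3}
        assert inverse_ecdf([3, 1, 2], 0.5) == 2

    def test_extremes(self):
        s = [4.0, -1.0, 2.5]
        assert inverse_ecdf(s, 1.0) == 4.0
        assert inverse_ecdf(s, 1 / 3) == -1.0

    @pytest.mark.parametrize("u", [0.0, -0.1, 1.01])
    def test_invalid_level(self, u):
        with pytest.raises(ValueError):
            inverse_ecdf([1.0], u)

    def test_inverse_is_generalized_inverse(self, rng):
        s = rng.normal(size=40)
        for u in rng.uniform(0.01, 1.0, size=20):
            v = inverse_ecdf(s, u)
            assert ecdf(s, v) >= u
            smaller = s[s < v]
            if smaller.size:
                assert ecdf(s, smaller.max()) < u


class TestWDistance:
    def test_identity(self, rng):
        a = rng.normal(size=17)
        assert w_distance(a, a) == 0.0

    def test_point_masses(self):
        assert w_distance([0, 0], [1, 1]) == pytest.approx(1.0)

    def test_lp_oracle_equivalence(self, rng):
        # exhaustive transport LP agrees with the rank-order formula
        for _ in range(100):
            na, nb = rng.integers(1, 11, size=2)
            a = rng.normal(size=na) * rng.uniform(0.5, 3)
            b = rng.normal(size=nb) + rng.uniform(-2, 2)
            assert w_distance(a, b) == pytest.approx(lp_transport_cost(a, b),
                                                     abs=1e-10)

    def test_scipy_cross_check(self, rng):
        a = rng.normal(size=300)
        b = rng.normal(size=170) * 2 + 1
        assert w_distance(a, b) == pytest.approx(scipy_w1(a, b), abs=1e-12)

    def test_outlier_influence_bounded(self, rng):
        a = rng.normal(size=1000)
        b = a.copy()
        b[0] = 1e6
        # rank-order boundedness: one corrupted point moves W1 by at most
        # its displacement over n
        assert abs(w_distance(a, b)) <= (1e6 + np.abs(a).max()) / 1000

    def test_higher_order(self):
        # k=2 on point masses: sqrt of mean squared quantile gap
        assert w_distance([0, 0], [1, 3], DistanceSpec(k=2)) == pytest.approx(
            np.sqrt((1 + 9) / 2))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.lists(st.floats(-50, 50), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_metric_axioms(self, a, b, c):
        dab = w_distance(a, b)
        dba = w_distance(b, a)
        assert dab >= 0
        assert dab == pytest.approx(dba, abs=1e-12)
        # triangle inequality
        assert dab <= w_distance(a, c) + w_distance(c, b) + 1e-9

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20),
           st.floats(-10, 10))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_translation_invariance(self, a, shift):
        b = [x + 1.0 for x in a]
        d0 = w_distance(a, b)
        d1 = w_distance([x + shift for x in a], [x + shift for x in b])
        assert d1 == pytest.approx(d0, abs=1e-9)
        # shifting one sample moves W1 by at most the shift
        assert abs(w_distance(a, [x + shift for x in a])) <= abs(shift) + 1e-9


class TestWindowed:
    def test_identical_sequences_all_zero(self, rng):
        a = rng.normal(size=1000)
        d = windowed_w_distance(a, a, DistanceSpec(window_len=256, window_step=128))
        assert d.shape == (6,)
        np.testing.assert_array_equal(d, 0.0)

    def test_single_full_window_equals_flat(self, rng):
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        d = windowed_w_distance(a, b, DistanceSpec(window_len=300, window_step=299))
        assert d.shape == (1,)
        assert d[0] == pytest.approx(w_distance(a, b))

    def test_burst_detected_by_max_window(self, rng):
        a = rng.normal(size=1024)
        b = a.copy()
        b[400:464] += 6.0  # localized burst
        spec = DistanceSpec(window_len=128, window_step=64)
        assert windowed_w_distance(a, b, spec).max() > w_distance(a, b)

    def test_window_longer_than_data(self, rng):
        with pytest.raises(ValueError, match="longer"):
            windowed_w_distance(rng.normal(size=10), rng.normal(size=10),
                                DistanceSpec(window_len=11, window_step=5))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DistanceSpec(window_len=10, window_step=10)
        with pytest.raises(ValueError):
            DistanceSpec(k=0)
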