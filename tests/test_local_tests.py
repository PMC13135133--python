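"""Exact hypergeometric tail tests and their attainable-value distributions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spatassoc.local_tests import (
    hypergeom_pvalues,
    hypergeom_pvalues_batch,
    min_achievable_pvalues,
    pvalue_support,
    support_bounds,
)


def enumerate_pvalues(n_ij, n_i, n_j, n_pin):
    """Independent oracle: enumerate every placement of species i's pinpoints
    against a fixed placement of species j, count overlaps."""
    j_set = set(range(n_j))
    total = math.comb(n_pin, n_i)
    ge = eq = le = 0
    for combo in itertools.combinations(range(n_pin), n_i):
        k = len(j_set.intersection(combo))
        ge += k >= n_ij
        le += k <= n_ij
    return ge / total, le / total


class TestTailValues:
    @pytest.mark.parametrize("k,ni,nj,n,expected_plus,expected_minus", [
        (2, 2, 2, 4, 1 / 6, 1.0),            # all four tables overlap fully
        (0, 2, 2, 4, 1.0, 1 / 6),            # mirrored extreme
        (5, 5, 5, 10, 1 / 252, 1.0),         # single most-extreme table
    ])
    def test_enumerated_examples(self, k, ni, nj, n, expected_plus,
                                 expected_minus):
        p_plus, p_minus = hypergeom_pvalues(k, ni, nj, n)
        assert p_plus == pytest.approx(expected_plus, abs=1e-12)
        assert p_minus == pytest.approx(expected_minus, abs=1e-12)

    def test_lower_support_bound_identities(self):
        # at k = k_min: p_minus = P(X = k_min), p_plus = 1
        p_plus, p_minus = hypergeom_pvalues(1, 4, 7, 10)  # k_min = 1
        sup = pvalue_support(4, 7, 10, "minus")
        assert p_plus == pytest.approx(1.0)
        assert p_minus == pytest.approx(sup.min_p)

    def test_outside_support_raises(self):
        with pytest.raises(ValueError):
            hypergeom_pvalues(3, 2, 2, 4)
        with pytest.raises(ValueError):
            hypergeom_pvalues(0, 4, 7, 10)  # k_min is 1

    @pytest.mark.parametrize("k,ni,nj,n", [
        (1, 3, 4, 9), (2, 5, 5, 12), (0, 2, 6, 11), (3, 3, 3, 8),
    ])
    def test_brute_force_enumeration_oracle(self, k, ni, nj, n):
        p_plus, p_minus = hypergeom_pvalues(k, ni, nj, n)
        bf_plus, bf_minus = enumerate_pvalues(k, ni, nj, n)
        assert p_plus == pytest.approx(bf_plus, abs=1e-12)
        assert p_minus == pytest.approx(bf_minus, abs=1e-12)

    def test_batch_matches_scalar(self, rng):
        ks, nis, njs = [], [], []
        for _ in range(50):
            ni, nj = rng.integers(1, 40, 2)
            lo, hi = support_bounds(ni, nj, 300)
            ks.append(rng.integers(lo, hi + 1)); nis.append(ni); njs.append(nj)
        bp, bm = hypergeom_pvalues_batch(ks, nis, njs, 300)
        for i in range(50):
            sp, sm = hypergeom_pvalues(ks[i], nis[i], njs[i], 300)
            assert bp[i] == pytest.approx(sp, rel=1e-12)
            assert bm[i] == pytest.approx(sm, rel=1e-12)


class TestSupport:
    def test_small_support_enumeration(self):
        sup = pvalue_support(2, 2, 4, "plus")
        np.testing.assert_allclose(sup.values, [1 / 6, 5 / 6, 1.0], atol=1e-12)
        np.testing.assert_allclose(sup.masses, [1 / 6, 4 / 6, 1 / 6],
                                   atol=1e-12)

    def test_degenerate_support_single_value(self):
        sup = pvalue_support(1, 10, 10, "plus")  # species j fills the plot
        assert sup.values.tolist() == [1.0]
        assert sup.masses.tolist() == [1.0]
        assert sup.is_degenerate

    @pytest.mark.parametrize("ni,nj,n,tail", [
        (3, 5, 20, "plus"), (3, 5, 20, "minus"), (10, 10, 30, "plus"),
        (30, 45, 300, "minus"),
    ])
    def test_masses_sum_to_one(self, ni, nj, n, tail):
        sup = pvalue_support(ni, nj, n, tail)
        assert sup.masses.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(sup.values) > 0)

    @given(ni=st.integers(1, 25), nj=st.integers(1, 25),
           tail=st.sampled_from(["plus", "minus"]))
    def test_superuniformity_at_attainable_values(self, ni, nj, tail):
        sup = pvalue_support(ni, nj, 25, tail)
        cdf = np.cumsum(sup.masses)
        assert np.all(cdf <= sup.values + 1e-9)

    @given(ni=st.integers(1, 20), nj=st.integers(1, 20))
    def test_monotone_in_overlap_and_symmetric(self, ni, nj):
        n = 20
        lo, hi = support_bounds(ni, nj, n)
        plus = [hypergeom_pvalues(k, ni, nj, n)[0] for k in range(lo, hi + 1)]
        minus = [hypergeom_pvalues(k, ni, nj, n)[1] for k in range(lo, hi + 1)]
        assert np.all(np.diff(plus) <= 1e-12)
        assert np.all(np.diff(minus) >= -1e-12)
        swapped = hypergeom_pvalues(lo, nj, ni, n)
        assert swapped == pytest.approx(hypergeom_pvalues(lo, ni, nj, n))


class TestMinAchievable:
    def test_rare_pair_closed_form(self):
        p_plus, p_minus = min_achievable_pvalues(3, 3, 300)
        assert p_plus == pytest.approx(1 / 4_455_100, rel=1e-9)
        # C(297,3)/C(300,3): rare pairs cannot show detectable segregation
        assert p_minus == pytest.approx(
            (297 * 296 * 295) / (300 * 299 * 298), rel=1e-12)

    def test_small_case(self):
        assert min_achievable_pvalues(2, 2, 4) == pytest.approx((1 / 6, 1 / 6))

    def test_saturating_pair_segregation_undetectable(self):
        p_plus, p_minus = min_achievable_pvalues(10, 10, 10)
        assert p_minus == pytest.approx(1.0)

    @given(ni=st.integers(1, 25), nj=st.integers(1, 25))
    def test_minima_are_support_minima(self, ni, nj):
        n = 25
        p_plus, p_minus = min_achievable_pvalues(ni, nj, n)
        assert p_plus == pytest.approx(
            pvalue_support(ni, nj, n, "plus").min_p, rel=1e-12)
        assert p_minus == pytest.approx(
            pvalue_support(ni, nj, n, "minus").min_p, rel=1e-12)
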