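"""Regional combination of discrete per-plot p-values."""

import math

import numpy as np
import pytest

from spatassoc.combine import (
    ExactCapacityError,
    combine_exact,
    combine_gamma,
    min_combined_pvalue,
    null_moments,
)
from spatassoc.local_tests import PvalueSupport, pvalue_support

THREE_POINT = pvalue_support(2, 2, 4, "plus")  # {1/6: 1/6, 5/6: 4/6, 1: 1/6}


def three_point_moments():
    """Independent enumeration of E and Var of −ln p over the 3-point support."""
    vals = [1 / 6, 5 / 6, 1.0]
    w = [1 / 6, 4 / 6, 1 / 6]
    x = [-math.log(v) for v in vals]
    mu = sum(wi * xi for wi, xi in zip(w, x))
    var = sum(wi * (xi - mu) ** 2 for wi, xi in zip(w, x))
    return mu, var


class TestNullMoments:
    def test_single_stratum_enumeration(self):
        mu, var = three_point_moments()
        got_mu, got_var, _ = null_moments([THREE_POINT])
        assert got_mu == pytest.approx(mu, abs=1e-12)
        assert got_var == pytest.approx(var, abs=1e-12)
        # matches the hand value ~0.42018 / ~0.38068
        assert got_mu == pytest.approx(0.42018, abs=1e-4)
        assert got_var == pytest.approx(0.38068, abs=1e-4)

    def test_fine_grid_uniform_limit(self):
        # −ln U ~ Exp(1): mean and variance both tend to 1 per stratum
        g = 20000
        sup = PvalueSupport(np.arange(1, g + 1) / g, np.full(g, 1 / g))
        mu, var, _ = null_moments([sup])
        assert mu == pytest.approx(1.0, abs=5e-3)
        assert var == pytest.approx(1.0, abs=2e-2)

    def test_independent_strata_add(self):
        mu1, var1, _ = null_moments([THREE_POINT])
        mu2, var2, _ = null_moments([THREE_POINT, THREE_POINT])
        assert mu2 == pytest.approx(2 * mu1, abs=1e-12)
        assert var2 == pytest.approx(2 * var1, abs=1e-12)

    def test_empty_is_domain_error(self):
        with pytest.raises(ValueError):
            null_moments([])


class TestExactConvolution:
    def test_two_strata_at_minimum(self):
        # only the double-extreme outcome reaches T_obs = 2 ln 6
        p = combine_exact([1 / 6, 1 / 6], [THREE_POINT, THREE_POINT])
        assert p == pytest.approx(1 / 36, abs=1e-12)

    def test_single_stratum_is_identity_on_support(self):
        # tail-probability p-values satisfy P(p <= v) = v at attainable v
        for v in THREE_POINT.values:
            assert combine_exact([v], [THREE_POINT]) == pytest.approx(
                v, abs=1e-12)

    def test_no_evidence_gives_one(self):
        assert combine_exact([1.0, 1.0], [THREE_POINT, THREE_POINT]) == 1.0

    def test_capacity_error(self):
        sup = pvalue_support(100, 100, 300, "plus")
        with pytest.raises(ExactCapacityError):
            combine_exact([sup.min_p] * 4, [sup] * 4, cap=10_000)


class TestGammaApproximation:
    def test_single_stratum_close_to_exact(self):
        for v in THREE_POINT.values[:-1]:
            p_g = combine_gamma([v], [THREE_POINT], "gamma2")
            assert abs(math.log10(p_g / v)) <= 0.3

    def test_two_strata_against_oracle(self):
        p_exact = combine_exact([1 / 6, 1 / 6], [THREE_POINT, THREE_POINT])
        p_g = combine_gamma([1 / 6, 1 / 6], [THREE_POINT, THREE_POINT])
        assert abs(math.log10(p_g / p_exact)) <= 0.5

    def test_all_ones_gives_one(self):
        assert combine_gamma([1.0, 1.0], [THREE_POINT, THREE_POINT]) == 1.0

    def test_degenerate_strata_contribute_nothing(self):
        degenerate = pvalue_support(1, 10, 10, "plus")  # support {1}
        sup = pvalue_support(4, 5, 20, "plus")
        p = sup.min_p
        for method in (combine_gamma, combine_exact):
            with_deg = method([p, 1.0], [sup, degenerate])
            without = method([p], [sup])
            assert with_deg == pytest.approx(without, rel=1e-12)

    def test_gamma3_valid_probability(self, rng):
        sups = [pvalue_support(int(rng.integers(2, 30)),
                               int(rng.integers(2, 30)), 60, "minus")
                for _ in range(5)]
        ps = [float(s.values[rng.choice(s.values.size, p=s.masses)])
              for s in sups]
        for variant in ("gamma2", "gamma3"):
            p = combine_gamma(ps, sups, variant)
            assert 0 < p <= 1


class TestMinCombined:
    def test_rare_pair_segregation_undetectable(self):
        p = min_combined_pvalue([(3, 3, 300)], "minus")
        assert p > 0.95  # cannot reach any usual alpha

    def test_rare_pair_aggregation_detectable(self):
        p = min_combined_pvalue([(3, 3, 300)], "plus", variant="exact")
        assert p == pytest.approx(1 / 4_455_100, rel=1e-6)
        # the gamma route is approximate but still flags the pair detectable
        assert min_combined_pvalue([(3, 3, 300)], "plus") < 0.05

    def test_adding_informative_plot_never_hurts(self):
        margins = [(10, 12, 300)]
        for tail in ("plus", "minus"):
            before = min_combined_pvalue(margins, tail)
            after = min_combined_pvalue(margins + [(10, 12, 300)], tail)
            assert after <= before + 1e-12

    def test_dominates_observed_combination(self, rng):
        # p_min_combined <= p_combined for any observed data, same method
        for _ in range(25):
            k = int(rng.integers(1, 4))
            margins = [(int(rng.integers(1, 40)), int(rng.integers(1, 40)), 300)
                       for _ in range(k)]
            for tail in ("plus", "minus"):
                sups = [pvalue_support(ni, nj, n, tail)
                        for ni, nj, n in margins]
                obs = [float(s.values[rng.choice(s.values.size, p=s.masses)])
                       for s in sups]
                for variant in ("gamma2", "exact"):
                    p_min = min_combined_pvalue(margins, tail, variant)
                    p_obs = (combine_exact(obs, sups) if variant == "exact"
                             else combine_gamma(obs, sups, variant))
                    assert p_min <= p_obs + 1e-12
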