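"""Per-plot exact tests of pairwise spatial aggregation / segregation.

Within one plot with ``N_s`` pinpoints, if species *i* occupies ``n_is``
pinpoints and species *j* occupies ``n_js`` and individuals are placed
independently of each other, the co-location count follows

    n_ijs ~ Hypergeometric(N_s, n_is, n_js)

One-tailed Fisher exact p-values are

    p_plus  = P(X >= n_ijs)   (aggregation: more shared pinpoints than chance)
    p_minus = P(X <= n_ijs)   (segregation: fewer shared pinpoints than chance)

Because the test is discrete, only finitely many p-values are attainable for
given margins; their null distribution (:class:`PvalueSupport`) drives the
evidence combination and discrete-FDR stages downstream.  No mid-p or
continuity correction is applied — superuniformity (P(p <= u) <= u) is
required for the combination step to be valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "PairPlotEvidence",
    "PvalueSupport",
    "hypergeom_pvalues",
    "hypergeom_pvalues_batch",
    "pvalue_support",
    "min_achievable_pvalues",
    "support_bounds",
]


def support_bounds(n_i: int, n_j: int, n_pin: int) -> tuple:
    """Attainable co-location range ``[k_min, k_max]`` for the margins."""
    return max(0, n_i + n_j - n_pin), min(n_i, n_j)


def _check_margins(n_i: int, n_j: int, n_pin: int) -> None:
    if not (0 <= n_i <= n_pin and 0 <= n_j <= n_pin):
        raise ValueError(f"invalid margins n_i={n_i}, n_j={n_j}, N={n_pin}")


def hypergeom_pvalues(n_ij: int, n_i: int, n_j: int, n_pin: int) -> tuple:
    """Exact one-tailed p-values (p_plus, p_minus) for one pair in one plot."""
    _check_margins(n_i, n_j, n_pin)
    k_min, k_max = support_bounds(n_i, n_j, n_pin)
    if not k_min <= n_ij <= k_max:
        raise ValueError(
            f"n_ij={n_ij} outside hypergeometric support [{k_min}, {k_max}]"
        )
    rv = hypergeom(n_pin, n_i, n_j)
    p_plus = float(rv.sf(n_ij - 1))
    p_minus = float(rv.cdf(n_ij))
    # tail sums can creep above 1 by rounding; p-values live in (0, 1]
    return min(p_plus, 1.0), min(p_minus, 1.0)


def hypergeom_pvalues_batch(n_ij, n_i, n_j, n_pin) -> tuple:
    """Vectorised version of :func:`hypergeom_pvalues` over aligned arrays."""
    n_ij = np.asarray(n_ij, dtype=int)
    n_i = np.asarray(n_i, dtype=int)
    n_j = np.asarray(n_j, dtype=int)
    n_pin = np.broadcast_to(np.asarray(n_pin, dtype=int), n_ij.shape)
    p_plus = hypergeom.sf(n_ij - 1, n_pin, n_i, n_j)
    p_minus = hypergeom.cdf(n_ij, n_pin, n_i, n_j)
    return np.minimum(p_plus, 1.0), np.minimum(p_minus, 1.0)


@dataclass(frozen=True)
class PvalueSupport:
    """Null distribution of a discrete test's p-value.

    ``values`` are the attainable p-values sorted increasingly in (0, 1];
    ``masses`` their null probabilities (summing to 1).  The null CDF
    ``F(u) = P(p <= u)`` is a step function that satisfies superuniformity
    F(u) <= u, with equality exactly at the attainable values.
    """

    values: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("support masses must sum to 1")

    @property
    def min_p(self) -> float:
        return float(self.values[0])

    @property
    def is_degenerate(self) -> bool:
        """True when the only attainable p-value is 1 (zero evidence)."""
        return self.values.size == 1 and self.values[0] >= 1.0 - 1e-12

    def cdf(self, u) -> np.ndarray:
        """Null CDF F(u) = total mass of attainable values <= u."""
        cum = np.concatenate([[0.0], np.cumsum(self.masses)])
        idx = np.searchsorted(self.values, np.asarray(u, dtype=float) * (1 + 1e-12),
                              side="right")
        return cum[idx]


@lru_cache(maxsize=200_000)
def pvalue_support(n_i: int, n_j: int, n_pin: int, tail: str) -> PvalueSupport:
    """Attainable p-values and their null masses for one tail.

    tail="plus" gives the distribution of p_plus = P(X >= k) over k in the
    support, tail="minus" that of p_minus = P(X <= k); duplicate attainable
    values (possible only for degenerate supports) are merged.
    """
    _check_margins(n_i, n_j, n_pin)
    k_min, k_max = support_bounds(n_i, n_j, n_pin)
    ks = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(ks, n_pin, n_i, n_j)
    pmf = pmf / pmf.sum()
    if tail == "plus":
        # P(X >= k): reverse cumulative sum, exact to float addition
        pvals = np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)
    elif tail == "minus":
        pvals = np.minimum(np.cumsum(pmf), 1.0)
    else:
        raise ValueError("tail must be 'plus' or 'minus'")
    order = np.argsort(pvals, kind="stable")
    values, masses = pvals[order], pmf[order]
    # merge numerically identical attainable values
    keep = np.concatenate([[True], np.diff(values) > 1e-15])
    group = np.cumsum(keep) - 1
    merged_masses = np.zeros(group[-1] + 1)
    np.add.at(merged_masses, group, masses)
    return PvalueSupport(values[keep], merged_masses)


def min_achievable_pvalues(n_i: int, n_j: int, n_pin: int) -> tuple:
    """Smallest p-value each tail can produce given the margins.

    The aggregation tail bottoms out at P(X = k_max) (all of the rarer
    species' pinpoints shared) and the segregation tail at P(X = k_min).
    Locally rare pairs therefore cannot show detectable segregation, and
    saturating pairs cannot show detectable aggregation.
    """
    _check_margins(n_i, n_j, n_pin)
    k_min, k_max = support_bounds(n_i, n_j, n_pin)
    p_min_plus = float(hypergeom.pmf(k_max, n_pin, n_i, n_j))
    p_min_minus = float(hypergeom.pmf(k_min, n_pin, n_i, n_j))
    return min(p_min_plus, 1.0), min(p_min_minus, 1.0)


@dataclass(frozen=True)
class PairPlotEvidence:
    """One pair's exact-test outcome in one plot."""

    plot_id: str
    n_ij: int
    n_i: int
    n_j: int
    n_pin: int
    p_plus: float
    p_minus: float

    @classmethod
    def from_counts(cls, plot_id, n_ij, n_i, n_j, n_pin) -> "PairPlotEvidence":
        p_plus, p_minus = hypergeom_pvalues(n_ij, n_i, n_j, n_pin)
        return cls(plot_id, n_ij, n_i, n_j, n_pin, p_plus, p_minus)

    def support(self, tail: str) -> PvalueSupport:
        return pvalue_support(self.n_i, self.n_j, self.n_pin, tail)

    def pvalue(self, tail: str) -> float:
        return self.p_plus if tail == "plus" else self.p_minus
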