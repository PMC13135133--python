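"""Combine per-plot discrete p-values into one regional p-value per tail.

The regional null states that a species pair is spatially independent in
every plot where it co-occurs.  Evidence is pooled with Fisher's statistic

    T = Σ_s −ln p_s

but, unlike the classical chi-square recipe, the per-plot p-values here are
*discrete*: under the null each p_s takes only the attainable values of its
hypergeometric tail, so T follows a stratified discrete null rather than a
gamma.  Two routes to the combined p-value P(T_null >= T_obs) are provided:

* a moment-matched gamma approximation on the exact stratified null
  (``gamma2`` matches mean and variance; ``gamma3`` a shifted gamma that also
  matches skewness), cheap at any number of plots;
* exact discrete convolution of the per-stratum distributions of −ln p,
  tractable for few plots / small supports, used as the authoritative
  reference.

Strata whose entire support is {1} carry no evidence and are dropped before
moment matching.  The gamma tail is clamped below at the exact floor
P(T = T_max) = Π_s mass(min p_s), so that the minimum-achievable combined
p-value always lower-bounds the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .local_tests import PairPlotEvidence, PvalueSupport, pvalue_support

__all__ = [
    "CombinedEvidence",
    "ExactCapacityError",
    "null_moments",
    "support_moments",
    "combine_gamma",
    "combine_exact",
    "combine_pvalues",
    "min_combined_pvalue",
]

DEFAULT_EXACT_CAP = 1_000_000
_MERGE_RTOL = 1e-9
_TINY = 1e-300  # p-values live in (0, 1]; guard against float underflow


class ExactCapacityError(RuntimeError):
    """Joint outcome space too large for exact convolution; use a gamma variant."""


@dataclass(frozen=True)
class CombinedEvidence:
    """Regional evidence for one pair and one tail."""

    species_i: str
    species_j: str
    tail: str
    t_obs: float
    n_plots: int
    p_combined: float
    method: str
    per_plot: tuple = field(default=())


def support_moments(support: PvalueSupport) -> tuple:
    """(mean, variance, third central moment) of −ln p over one support."""
    x = -np.log(support.values)
    w = support.masses
    mu = float(np.sum(w * x))
    c = x - mu
    var = float(np.sum(w * c**2))
    m3 = float(np.sum(w * c**3))
    return mu, var, m3


def null_moments(supports: list) -> tuple:
    """Exact null moments of T = Σ −ln p across independent strata.

    Returns (mu, sigma2, gamma1): mean, variance and skewness of T.  Strata
    are independent, so means, variances and third central moments add.
    """
    if not supports:
        raise ValueError("need at least one p-value support")
    mu = var = m3 = 0.0
    for s in supports:
        m, v, t = support_moments(s)
        mu += m
        var += v
        m3 += t
    gamma1 = m3 / var**1.5 if var > 0 else 0.0
    return mu, var, gamma1


def _extreme_floor(supports: list) -> float:
    """Exact P(T = T_max): every stratum at its minimum attainable p."""
    log_floor = 0.0
    for s in supports:
        log_floor += math.log(s.masses[0]) if s.masses[0] > 0 else -math.inf
    return math.exp(log_floor)


def _gamma_tail(t_obs: float, mu: float, var: float, gamma1: float,
                variant: str) -> float:
    if variant == "gamma2":
        shape = mu**2 / var
        scale = var / mu
        return float(gamma_dist.sf(t_obs, shape, scale=scale))
    if variant == "gamma3":
        if abs(gamma1) < 1e-12:
            return float(gamma_dist.sf(t_obs, mu**2 / var, scale=var / mu))
        shape = 4.0 / gamma1**2
        scale = math.sqrt(var / shape)
        shift = mu - shape * scale
        return float(gamma_dist.sf(max(t_obs - shift, 0.0), shape, scale=scale))
    raise ValueError("variant must be 'gamma2' or 'gamma3'")


def _active(pvalues, supports):
    """Drop zero-evidence strata (support == {1})."""
    keep = [(p, s) for p, s in zip(pvalues, supports) if not s.is_degenerate]
    if not keep:
        return [], []
    ps, ss = zip(*keep)
    return list(ps), list(ss)


def combine_gamma(pvalues: list, supports: list, variant: str = "gamma2") -> float:
    """Moment-matched gamma upper tail of T = Σ −ln p at the observed value."""
    if len(pvalues) != len(supports) or not pvalues:
        raise ValueError("pvalues and supports must align and be non-empty")
    pvalues, supports = _active(pvalues, supports)
    if not supports:
        return 1.0
    t_obs = float(np.sum(-np.log(pvalues)))
    if t_obs <= 0.0:
        return 1.0
    mu, var, gamma1 = null_moments(supports)
    if var <= 0.0:
        return 1.0
    p = _gamma_tail(t_obs, mu, var, gamma1, variant)
    # keep the gamma tail above the exact most-extreme-outcome mass
    return float(min(1.0, max(p, _extreme_floor(supports), _TINY)))


def _convolve(values_a, masses_a, values_b, masses_b, cap: int):
    t = np.add.outer(values_a, values_b).ravel()
    m = np.multiply.outer(masses_a, masses_b).ravel()
    order = np.argsort(t, kind="stable")
    t, m = t[order], m[order]
    # merge atoms whose T agree within relative tolerance
    scale = np.maximum(1.0, np.abs(t[:-1]))
    new_atom = np.concatenate([[True], np.diff(t) > _MERGE_RTOL * scale])
    group = np.cumsum(new_atom) - 1
    merged_t = t[new_atom]
    merged_m = np.zeros(group[-1] + 1)
    np.add.at(merged_m, group, m)
    if merged_t.size > cap:
        raise ExactCapacityError(
            f"exact convolution grid has {merged_t.size} atoms (cap {cap}); "
            "use combine_gamma instead"
        )
    return merged_t, merged_m


def combine_exact(pvalues: list, supports: list,
                  cap: int = DEFAULT_EXACT_CAP) -> float:
    """Exact combined p-value P(T_null >= T_obs) by discrete convolution.

    Enumerates the joint distribution of T over the product of the
    per-stratum supports (with value-grid merging); intended as the
    authoritative oracle for few plots or small supports.
    """
    if len(pvalues) != len(supports) or not pvalues:
        raise ValueError("pvalues and supports must align and be non-empty")
    pvalues, supports = _active(pvalues, supports)
    if not supports:
        return 1.0
    t_obs = float(np.sum(-np.log(pvalues)))
    t_grid = np.array([0.0])
    m_grid = np.array([1.0])
    for s in supports:
        t_grid, m_grid = _convolve(t_grid, m_grid, -np.log(s.values), s.masses, cap)
    tol = _MERGE_RTOL * max(1.0, abs(t_obs))
    p = float(m_grid[t_grid >= t_obs - tol].sum())
    return min(1.0, max(p, _TINY))


def combine_pvalues(pvalues: list, supports: list, variant: str = "gamma2",
                    cap: int = DEFAULT_EXACT_CAP) -> float:
    """Dispatch on variant in {gamma2, gamma3, exact}."""
    if variant == "exact":
        return combine_exact(pvalues, supports, cap=cap)
    return combine_gamma(pvalues, supports, variant=variant)


def combine_evidence(evidence: list, tail: str, variant: str = "gamma2",
                     cap: int = DEFAULT_EXACT_CAP) -> CombinedEvidence:
    """Combine a pair's :class:`PairPlotEvidence` records for one tail."""
    if not evidence:
        raise ValueError("need at least one plot of evidence")
    pvalues = [e.pvalue(tail) for e in evidence]
    supports = [e.support(tail) for e in evidence]
    p = combine_pvalues(pvalues, supports, variant=variant, cap=cap)
    active_p, _ = _active(pvalues, supports)
    t_obs = float(np.sum(-np.log(active_p))) if active_p else 0.0
    e0 = evidence[0]
    return CombinedEvidence(
        species_i=getattr(e0, "species_i", ""),
        species_j=getattr(e0, "species_j", ""),
        tail=tail,
        t_obs=t_obs,
        n_plots=len(evidence),
        p_combined=p,
        method=variant,
        per_plot=tuple(evidence),
    )


def min_combined_pvalue(margins: list, tail: str, variant: str = "gamma2",
                        cap: int = DEFAULT_EXACT_CAP) -> float:
    """Best combined p-value attainable given the per-plot margins.

    Each plot's p-value is set to its minimum attainable value and the
    result combined with the same method used for observed data; pairs whose
    minimum exceeds the significance threshold can never be detected and are
    excluded upstream.

    ``margins`` is a list of (n_i, n_j, n_pinpoints) triples, one per plot
    where the pair co-occurs.
    """
    supports = [pvalue_support(ni, nj, npin, tail) for ni, nj, npin in margins]
    pvalues = [s.min_p for s in supports]
    return combine_pvalues(pvalues, supports, variant=variant, cap=cap)
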