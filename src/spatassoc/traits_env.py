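"""Trait-space characterisation of network roles and abiotic modelling.

Covers four analyses: (i) PCA of centred/scaled traits with pairwise
PERMANOVA contrasts of block centroids; (ii) functional rarity — per-plot
scarcity and abundance-weighted functional distinctiveness — with rank-test
group contrasts; (iii) quasi-Poisson modelling of per-plot association
richness against abiotic covariates with stepwise selection; and (iv)
hierarchical partitioning of the explained variance among predictors.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, mannwhitneyu
from skbio import DistanceMatrix
from skbio.stats.distance import permanova

from .network import adjusted_deviance_r2
from .screening import bh_adjust

__all__ = [
    "trait_pca",
    "pairwise_permanova",
    "functional_rarity",
    "group_contrasts",
    "association_richness_model",
    "hierarchical_partition",
]


def trait_pca(traits: pd.DataFrame) -> dict:
    """PCA of centred and scaled traits (correlation-matrix PCA).

    Returns loadings (traits × components), scores (species × components)
    and the variance fraction of each axis.  Species with any missing trait
    are dropped; a constant trait column is an error (it cannot be scaled).
    """
    x = traits.dropna()
    if x.shape[0] < 3:
        raise ValueError("need at least 3 species with complete traits")
    sd = x.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant trait column(s): {constant}")
    z = (x - x.mean()) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s**2 / (x.shape[0] - 1)
    frac = var / var.sum()
    comps = [f"PC{i+1}" for i in range(len(s))]
    return {
        "loadings": pd.DataFrame(vt.T, index=x.columns, columns=comps),
        "scores": pd.DataFrame(u * s, index=x.index, columns=comps),
        "variance_fraction": pd.Series(frac, index=comps),
    }


def pairwise_permanova(points, groups: pd.Series, n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """Pairwise PERMANOVA between group centroids in a (trait) space.

    ``points`` is either a species × coordinates DataFrame (Euclidean
    distances are taken) or a precomputed skbio DistanceMatrix.  Each pair
    of groups with >= 2 members per side is tested by label permutation;
    p-values are BH-adjusted across group pairs.  Groups with a single
    member are skipped with a warning.
    """
    if isinstance(points, DistanceMatrix):
        dm_full = points
        ids = list(dm_full.ids)
    else:
        ids = [str(i) for i in points.index]
        dm_full = DistanceMatrix(squareform(pdist(points.to_numpy())), ids)
    groups = groups.copy()
    groups.index = groups.index.astype(str)
    rows = []
    levels = sorted(groups.dropna().unique())
    for g1, g2 in itertools.combinations(levels, 2):
        members = [i for i in ids if groups.get(i) in (g1, g2)]
        n1 = sum(groups[i] == g1 for i in members)
        n2 = len(members) - n1
        if min(n1, n2) < 2:
            warnings.warn(f"group pair ({g1}, {g2}) skipped: a group has < 2 members")
            continue
        sub = dm_full.filter(members)
        grouping = [str(groups[i]) for i in sub.ids]
        res = permanova(sub, grouping, permutations=n_perm, seed=seed)
        rows.append({
            "group_1": g1,
            "group_2": g2,
            "pseudo_F": float(res["test statistic"]),
            "p_value": float(res["p-value"]),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def functional_rarity(traits: pd.DataFrame, abundance: pd.DataFrame,
                      trait_subset: list | None = None,
                      distances: pd.DataFrame | None = None) -> dict:
    """Per-plot scarcity and functional distinctiveness.

    Distances are Euclidean on z-scored traits, rescaled to [0, 1] by the
    observed maximum.  Within each plot with relative abundances a:

        D_is = Σ_{j≠i} d_ij a_js / Σ_{j≠i} a_js        (distinctiveness)
        S_is = exp(−R_s · ln 2 · a_is)                  (scarcity)

    with R_s the plot's species richness, so a species holding 1/R_s of the
    contacts scores S = 0.5.  A species alone in its plot has undefined
    distinctiveness (NaN).  Species never observed are excluded with a
    warning.  A precomputed distance matrix (species × species DataFrame,
    already in [0, 1]) may be supplied instead of traits.  Returns per-plot
    tables and per-species means over occupied plots.
    """
    cols = trait_subset or list(traits.columns)
    t = traits[cols].dropna()
    observed = abundance.columns[(abundance > 0).any(axis=0)]
    dropped = [s for s in t.index if s not in observed]
    if dropped:
        warnings.warn(f"{len(dropped)} species absent everywhere excluded")
    species = [s for s in t.index if s in observed]
    if distances is not None:
        d_df = distances.loc[species, species]
    else:
        t = t.loc[species]
        z = (t - t.mean()) / t.std(ddof=1).replace(0.0, 1.0)
        d = squareform(pdist(z.to_numpy()))
        if d.max() > 0:
            d = d / d.max()
        d_df = pd.DataFrame(d, index=species, columns=species)
    rows = []
    for plot in abundance.index:
        ab = abundance.loc[plot]
        present_all = ab[ab > 0]
        rel_all = present_all / present_all.sum()
        richness = len(present_all)
        present = [s for s in present_all.index if s in d_df.index]
        for s in present:
            a_i = rel_all[s]
            others = [o for o in present if o != s]
            if others:
                w = rel_all[others].to_numpy()
                dist = d_df.loc[s, others].to_numpy()
                dist_i = float(np.sum(dist * w) / np.sum(w))
            else:
                dist_i = np.nan
            rows.append({
                "plot_id": plot,
                "species_id": s,
                "distinctiveness": dist_i,
                "scarcity": math.exp(-richness * math.log(2) * a_i),
            })
    per_plot = pd.DataFrame(rows)
    means = (
        per_plot.groupby("species_id")[["distinctiveness", "scarcity"]].mean()
        if not per_plot.empty else pd.DataFrame()
    )
    return {"per_plot": per_plot, "per_species": means}


def group_contrasts(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum between every pair of groups, plus a
    global Kruskal–Wallis row; BH adjustment across the pairwise tests."""
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    levels = sorted(df["group"].unique())
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        a = df.loc[df["group"] == g1, "value"]
        b = df.loc[df["group"] == g2, "value"]
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"group_1": g1, "group_2": g2, "test": "wilcoxon",
                     "statistic": float(stat), "p_value": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    if len(levels) > 2:
        samples = [df.loc[df["group"] == g, "value"] for g in levels]
        stat, p = kruskal(*samples)
        out = pd.concat([out, pd.DataFrame([{
            "group_1": "all", "group_2": "all", "test": "kruskal",
            "statistic": float(stat), "p_value": float(p), "q_value": np.nan,
        }])], ignore_index=True)
    return out


# --- association-richness GLM -------------------------------------------------

@dataclass
class AssociationRichnessModel:
    """Baseline vs. full quasi-Poisson model of per-plot association counts."""

    coefficients: pd.DataFrame
    r2_baseline: float
    r2_full: float
    selected_terms: list
    partition_shares: pd.Series
    dispersion: float


def _design(env: pd.DataFrame, terms: list) -> pd.DataFrame:
    cols = {}
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols[term] = env[a] * env[b]
        else:
            cols[term] = env[term]
    return pd.DataFrame(cols, index=env.index)


def _fit_quasipoisson(y, x):
    exog = sm.add_constant(x, has_constant="add")
    return sm.GLM(y, exog, family=sm.families.Poisson()).fit(scale="X2")


def _adj_r2_for_terms(y, env, terms, null_dev, n):
    if not terms:
        return 0.0
    fit = _fit_quasipoisson(y, _design(env, terms))
    return adjusted_deviance_r2(fit, null_dev, n, len(terms) + 1)


def _stepwise(y, env, candidate_terms, forced, null_dev, n,
              min_improvement=0.01):
    """Both-direction search from the full model, maximising adjusted R².

    A term enters only if it raises adjusted R² by more than
    ``min_improvement``, and is dropped whenever removing it costs no more
    than that margin — adjusted R² alone rewards 1-df noise terms too
    readily, so a parsimony margin keeps null covariates out.
    """
    current = list(candidate_terms)
    best = _adj_r2_for_terms(y, env, forced + current, null_dev, n)
    improved = True
    n_moves = 0
    while improved and n_moves < 50:
        improved = False
        n_moves += 1
        moves = [("drop", t) for t in current] + [
            ("add", t) for t in candidate_terms if t not in current
        ]
        for action, term in moves:
            trial = ([t for t in current if t != term] if action == "drop"
                     else current + [term])
            # interactions may only stay alongside their main effects
            mains = {m for t in trial if ":" in t for m in t.split(":")}
            if not mains <= set(forced) | set(trial):
                continue
            r2 = _adj_r2_for_terms(y, env, forced + trial, null_dev, n)
            gain = r2 - best
            accept = (gain > -min_improvement if action == "drop"
                      else gain > min_improvement)
            if accept:
                best, current, improved = r2, trial, True
                break
    return current, _adj_r2_for_terms(y, env, forced + current, null_dev, n)


def association_richness_model(n_asso: pd.Series, environment: pd.DataFrame,
                               abiotic: list | None = None,
                               interactions: list | None = None,
                               collinearity_limit: float = 0.95,
                               stepwise: bool = True) -> AssociationRichnessModel:
    """Model per-plot counts of locally significant associations.

    The baseline model regresses ``n_asso`` on the plot's individual count
    alone (log link, quasi-Poisson); the full model adds abiotic covariates
    and the requested interactions (``"n_individuals:ETP"``-style names),
    pruned by both-direction stepwise search on adjusted deviance-R².
    Highly collinear abiotic pairs (|r| > ``collinearity_limit``) raise an
    error telling the caller to drop one.
    """
    plots = n_asso.index.intersection(environment.index)
    env = environment.loc[plots].astype(float)
    if abiotic is None:
        abiotic = [c for c in env.columns if c != "n_individuals"]
    keep = env[["n_individuals"] + abiotic].notna().all(axis=1)
    plots, env = plots[keep], env.loc[keep]
    y = n_asso.loc[plots].to_numpy(dtype=float)
    n = len(plots)
    n_terms = 1 + len(abiotic) + len(interactions or [])
    if n < n_terms + 3:
        raise ValueError(
            f"{n} plots cannot support {n_terms} candidate terms; "
            "reduce the abiotic covariate set"
        )
    corr = env[abiotic].corr().abs()
    for a, b in itertools.combinations(abiotic, 2):
        if corr.loc[a, b] > collinearity_limit:
            raise ValueError(
                f"predictors {a} and {b} are collinear (|r| = {corr.loc[a, b]:.3f}"
                f" > {collinearity_limit}); drop one before fitting"
            )
    null_dev = _fit_quasipoisson(y, pd.DataFrame(index=plots)).deviance
    forced = ["n_individuals"]
    base_fit = _fit_quasipoisson(y, _design(env, forced))
    r2_base = adjusted_deviance_r2(base_fit, null_dev, n, 2)
    candidates = list(abiotic) + list(interactions or [])
    if stepwise:
        selected, r2_full = _stepwise(y, env, candidates, forced, null_dev, n)
    else:
        selected = candidates
        r2_full = _adj_r2_for_terms(y, env, forced + selected, null_dev, n)
    terms = forced + selected
    full_fit = _fit_quasipoisson(y, _design(env, terms))
    coefs = pd.DataFrame({
        "coefficient": full_fit.params,
        "p_value": full_fit.pvalues,
    })
    shares = hierarchical_partition(
        lambda subset: _adj_r2_for_terms(y, env, list(subset), null_dev, n),
        terms,
    )
    return AssociationRichnessModel(
        coefficients=coefs,
        r2_baseline=float(r2_base),
        r2_full=float(r2_full),
        selected_terms=selected,
        partition_shares=shares,
        dispersion=float(full_fit.scale),
    )


def hierarchical_partition(r2_of_subset, predictors: list) -> pd.Series:
    """Independent contribution of each predictor to the model's R².

    Shapley-value averaging: each predictor's share is its mean incremental
    R² over all orderings of entry, computed by all-subsets enumeration with
    level weights.  Shares telescope exactly to the full-model R² (the
    empty-model R² is 0 by construction).  Limited to 8 predictors.
    """
    p = len(predictors)
    if p == 0:
        return pd.Series(dtype=float)
    if p > 8:
        raise ValueError("hierarchical partitioning limited to 8 predictors")
    cache = {}

    def r2(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = float(r2_of_subset(sorted(subset)))
        return cache[subset]

    shares = {}
    others_all = {t: [q for q in predictors if q != t] for t in predictors}
    for term in predictors:
        total = 0.0
        others = others_all[term]
        for r in range(len(others) + 1):
            weight = (math.factorial(r) * math.factorial(p - r - 1)
                      / math.factorial(p))
            for combo in itertools.combinations(others, r):
                s = frozenset(combo)
                total += weight * (r2(s | {term}) - r2(s))
        shares[term] = total
    return pd.Series(shares, name="r2_share")
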