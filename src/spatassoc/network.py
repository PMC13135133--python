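"""Signed regional association network: metrics, null models, group GLMs.

Species are nodes; a significant regional aggregation (positive) or
segregation (negative) is an undirected link, with pairs significant in both
tails kept as a single link flagged "both".  Connectance is reported against
two denominators: all co-occurring pairs (the set of testable links), and
co-occurring pairs restricted to the associated species themselves.  Observed
clustering (global transitivity) and node degrees are benchmarked against
Erdős–Rényi G(n, m) ensembles with matching node and link counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .screening import bh_adjust

__all__ = [
    "AssociationNetwork",
    "NullEnsemble",
    "build_network",
    "er_null_ensemble",
    "er_null_tests",
    "group_abundance_models",
    "adjusted_deviance_r2",
]


@dataclass
class AssociationNetwork:
    """The signed regional network plus its headline metrics."""

    graph: nx.Graph
    n_cooccurring_pairs: int
    n_cooccurring_pairs_associated: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> dict:
        return dict(self.graph.degree())

    @property
    def connectance(self) -> float:
        """Realised links over all co-occurring pairs."""
        if self.n_cooccurring_pairs == 0:
            return 0.0
        return self.n_edges / self.n_cooccurring_pairs

    @property
    def connectance_associated(self) -> float:
        """Realised links over co-occurring pairs among associated species."""
        if self.n_cooccurring_pairs_associated == 0:
            return 0.0
        return self.n_edges / self.n_cooccurring_pairs_associated

    @property
    def clustering(self) -> float:
        """Global transitivity: 3 × triangles / connected triples."""
        return nx.transitivity(self.graph)

    def sign_counts(self) -> dict:
        counts = {"positive": 0, "negative": 0, "both": 0}
        for _, _, s in self.graph.edges(data="sign"):
            counts[s] += 1
        return counts


def build_network(associations: list, cooccurring: list) -> AssociationNetwork:
    """Assemble the signed network from regional calls.

    Parameters
    ----------
    associations:
        :class:`~spatassoc.screening.CombinedAssociation` records.
    cooccurring:
        Output of :func:`~spatassoc.survey.cooccurring_pairs`; defines the
        connectance denominators.
    """
    g = nx.Graph()
    for a in associations:
        if a.sign == "none":
            continue
        if a.species_i == a.species_j:
            raise ValueError("self-association is not a valid edge")
        g.add_edge(a.species_i, a.species_j, sign=a.sign)
    nodes = set(g.nodes)
    n_co = len(cooccurring)
    n_co_assoc = sum(1 for i, j, _ in cooccurring if i in nodes and j in nodes)
    return AssociationNetwork(g, n_co, n_co_assoc)


@dataclass
class NullEnsemble:
    """Erdős–Rényi G(n, m) reference distributions."""

    n_replicates: int
    clustering: np.ndarray
    degrees: np.ndarray  # pooled over replicates and nodes
    seed: int


def _er_adjacency(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Dense adjacency of a uniform G(n, m) draw."""
    idx = rng.choice(n * (n - 1) // 2, size=m, replace=False)
    rows, cols = np.triu_indices(n, k=1)
    a = np.zeros((n, n), dtype=np.int8)
    a[rows[idx], cols[idx]] = 1
    return a | a.T


def _transitivity(a: np.ndarray) -> float:
    deg = a.sum(axis=1)
    triples = float(np.sum(deg * (deg - 1)) / 2)
    if triples == 0:
        return 0.0
    triangles = float(np.trace(a @ a @ a)) / 6.0
    return 3.0 * triangles / triples


def er_null_ensemble(n: int, m: int, n_replicates: int = 999,
                     seed: int = 0) -> NullEnsemble:
    """Clustering values and pooled degrees of G(n, m) replicates."""
    if m > n * (n - 1) // 2:
        raise ValueError("more edges than node pairs")
    rng = np.random.default_rng(seed)
    clus = np.empty(n_replicates)
    degs = np.empty((n_replicates, n), dtype=np.int32)
    for r in range(n_replicates):
        a = _er_adjacency(n, m, rng)
        clus[r] = _transitivity(a)
        degs[r] = a.sum(axis=1)
    return NullEnsemble(n_replicates, clus, degs.ravel(), seed)


def er_null_tests(net: AssociationNetwork, n_replicates: int = 999,
                  seed: int = 0, alpha: float = 0.05) -> dict:
    """Clustering and degree significance against the ER null.

    Empirical upper-tail p-values use the add-one rule
    p = (1 + #{null >= observed}) / (n_replicates + 1); node degrees are
    compared against the pooled null degree distribution (all nodes of
    G(n, m) are exchangeable) and hub species are those with BH-corrected
    p <= alpha.
    """
    if net.n_edges < 1:
        raise ValueError("network has no edges")
    ens = er_null_ensemble(net.n_nodes, net.n_edges, n_replicates, seed)
    obs_c = net.clustering
    p_clustering = (1 + np.sum(ens.clustering >= obs_c - 1e-12)) / (n_replicates + 1)
    nodes = sorted(net.graph.nodes)
    degs = np.array([net.graph.degree(v) for v in nodes])
    pooled = np.sort(ens.degrees)
    # P(null degree >= d) via searchsorted on the pooled sample
    n_pool = pooled.size
    n_ge = n_pool - np.searchsorted(pooled, degs, side="left")
    p_deg = (1 + n_ge) / (n_pool + 1)
    q_deg = bh_adjust(p_deg)
    hubs = [v for v, q in zip(nodes, q_deg) if q <= alpha]
    return {
        "p_clustering": float(p_clustering),
        "observed_clustering": float(obs_c),
        "null_clustering_mean": float(ens.clustering.mean()),
        "degree_pvalues": dict(zip(nodes, p_deg)),
        "degree_qvalues": dict(zip(nodes, q_deg)),
        "hubs": hubs,
        "ensemble": ens,
    }


def adjusted_deviance_r2(fit, null_deviance: float, n: int, n_params: int) -> float:
    """Deviance-based adjusted R² for a GLM:
    1 − (D_res/(n−p)) / (D_null/(n−1))."""
    if n - n_params <= 0:
        return np.nan
    return 1.0 - (fit.deviance / (n - n_params)) / (null_deviance / (n - 1))


def _quasipoisson_fit(y: np.ndarray, x: pd.DataFrame):
    exog = sm.add_constant(x, has_constant="add")
    model = sm.GLM(y, exog, family=sm.families.Poisson())
    fit = model.fit(scale="X2")  # Pearson chi2 / df dispersion
    return fit


def group_abundance_models(groups: dict, abundance: pd.DataFrame,
                           environment: pd.DataFrame,
                           covariates: list | None = None) -> pd.DataFrame:
    """Per-group quasi-Poisson GLMs of block abundance vs. abiotic context.

    For each block, the summed pinpoint-contact count of its member species
    per plot is modelled with a log link: a baseline model with the plot's
    total individual count as sole predictor, and a full model adding the
    abiotic covariates.  Overdispersion is absorbed by the Pearson-χ²/df
    scale.  Reports adjusted deviance-R² of both models and their difference.
    """
    plots = abundance.index.intersection(environment.index)
    if len(plots) == 0:
        raise ValueError("abundance and environment share no plots")
    if covariates is None:
        covariates = [c for c in environment.columns if c != "n_individuals"]
    if len(plots) < len(covariates) + 3:
        raise ValueError(
            f"{len(plots)} plots cannot support {len(covariates)} abiotic "
            "covariates plus the individual count; reduce the covariate set"
        )
    env = environment.loc[plots, covariates].astype(float)
    keep = env.notna().all(axis=1)
    plots = plots[keep]
    env = env.loc[plots]
    total = abundance.loc[plots].sum(axis=1).to_numpy(dtype=float)
    rows = []
    for block in sorted(set(groups.values())):
        members = [s for s, b in groups.items() if b == block
                   and s in abundance.columns]
        y = abundance.loc[plots, members].sum(axis=1).to_numpy(dtype=float)
        base_x = pd.DataFrame({"n_individuals": total}, index=plots)
        full_x = base_x.join(env)
        null_dev = _quasipoisson_fit(y, pd.DataFrame(index=plots)).deviance
        base = _quasipoisson_fit(y, base_x)
        full = _quasipoisson_fit(y, full_x)
        n = len(plots)
        r2_base = adjusted_deviance_r2(base, null_dev, n, base_x.shape[1] + 1)
        r2_full = adjusted_deviance_r2(full, null_dev, n, full_x.shape[1] + 1)
        coefs = {f"coef_{k}": v for k, v in full.params.items() if k != "const"}
        rows.append({
            "block": block,
            "n_species": len(members),
            "r2_baseline": r2_base,
            "r2_full": r2_full,
            "delta_r2": r2_full - r2_base,
            "dispersion": full.scale,
            **coefs,
        })
    return pd.DataFrame(rows).set_index("block")
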