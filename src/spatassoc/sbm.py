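"""Bernoulli stochastic block model for mesoscale network roles.

The SBM assigns each species to one of K latent blocks; an edge between
species in blocks k and l appears independently with probability Π_kl.  The
model is fitted on the unsigned skeleton of the association network by
variational EM (mean-field), with spectral and random restarts, and K is
selected by the integrated completed likelihood (ICL).  Blocks are reported
in decreasing mean-degree order; when the selected K is 3 they are named
core / subordinate / peripheral, the taxonomy that emerges in centralised
plant association networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

__all__ = ["BlockFit", "fit_sbm", "icl_score"]

_EPS = 1e-9
ROLE_NAMES = ("core", "subordinate", "peripheral")


@dataclass
class BlockFit:
    """Fitted block structure of an association network."""

    n_blocks: int
    memberships: dict            # node -> block (0-based, degree-ordered)
    pi: np.ndarray               # K×K block connection probabilities
    icl: float
    elbo: float
    icl_by_k: dict = field(default_factory=dict)
    block_mean_degree: np.ndarray = None
    block_mean_degree_se: np.ndarray = None
    within_connectance: np.ndarray = None  # NaN for blocks with < 2 members
    roles: dict = field(default_factory=dict)  # block -> role name (K == 3)

    @property
    def block_sizes(self) -> np.ndarray:
        z = np.array(list(self.memberships.values()))
        return np.bincount(z, minlength=self.n_blocks)


def _as_adjacency(graph) -> tuple:
    if isinstance(graph, nx.Graph):
        nodes = sorted(graph.nodes)
        a = nx.to_numpy_array(graph, nodelist=nodes, dtype=float)
        np.fill_diagonal(a, 0.0)
        return a, nodes
    a = np.asarray(graph, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a = np.where(a > 0, 1.0, 0.0)
    np.fill_diagonal(a, 0.0)
    a = np.maximum(a, a.T)
    return a, list(range(a.shape[0]))


def _m_step(a: np.ndarray, tau: np.ndarray) -> tuple:
    prop = np.clip(tau.mean(axis=0), _EPS, None)
    prop = prop / prop.sum()
    edge_kl = tau.T @ a @ tau
    tot = tau.sum(axis=0)
    dyads_kl = np.outer(tot, tot) - tau.T @ tau
    pi = np.clip(edge_kl / np.maximum(dyads_kl, _EPS), _EPS, 1 - _EPS)
    pi = (pi + pi.T) / 2
    return prop, pi


def _e_step(a: np.ndarray, tau: np.ndarray, prop: np.ndarray,
            pi: np.ndarray) -> np.ndarray:
    log_pi = np.log(pi)
    log_1mpi = np.log1p(-pi)
    s = tau.sum(axis=0)
    pos = a @ tau @ log_pi.T
    neg = (s[None, :] - tau - a @ tau) @ log_1mpi.T
    logits = np.log(prop)[None, :] + pos + neg
    logits -= logits.max(axis=1, keepdims=True)
    t = np.exp(logits)
    return t / t.sum(axis=1, keepdims=True)


def _elbo(a: np.ndarray, tau: np.ndarray, prop: np.ndarray,
          pi: np.ndarray) -> float:
    log_pi, log_1mpi = np.log(pi), np.log1p(-pi)
    s = tau.sum(axis=0)
    pos = np.sum((tau.T @ a @ tau) * log_pi)
    dyads = np.outer(s, s) - tau.T @ tau
    neg = np.sum((dyads - tau.T @ a @ tau) * log_1mpi)
    entropy = -np.sum(tau * np.log(np.clip(tau, _EPS, None)))
    mixing = np.sum(tau * np.log(prop)[None, :])
    return float(0.5 * (pos + neg) + mixing + entropy)


def _vem(a: np.ndarray, tau0: np.ndarray, max_iter: int = 200,
         tol: float = 1e-6) -> tuple:
    tau = tau0.copy()
    prop, pi = _m_step(a, tau)
    for _ in range(max_iter):
        new_tau = _e_step(a, tau, prop, pi)
        delta = np.abs(new_tau - tau).max()
        tau = 0.5 * tau + 0.5 * new_tau  # damped fixed point
        prop, pi = _m_step(a, tau)
        if delta < tol:
            break
    return tau, prop, pi, _elbo(a, tau, prop, pi)


def _spectral_tau(a: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = a.shape[0]
    if k == 1:
        return np.ones((n, 1))
    deg = a.sum(axis=1)
    # regularised symmetric Laplacian embedding
    d = 1.0 / np.sqrt(deg + deg.mean() + 1.0)
    sym = (a + np.full_like(a, deg.mean() / n)) * np.outer(d, d)
    w, v = eigh(sym)
    emb = v[:, -k:]
    km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(emb)
    return _labels_to_tau(labels, k)


def _labels_to_tau(labels: np.ndarray, k: int) -> np.ndarray:
    tau = np.full((labels.size, k), 0.05 / max(k - 1, 1))
    tau[np.arange(labels.size), labels] = 0.95
    return tau / tau.sum(axis=1, keepdims=True)


def icl_score(a: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Integrated completed likelihood of a hard partition.

    Completed Bernoulli log-likelihood at the MLE given the partition, minus
    (K(K+1)/4)·log(n(n−1)/2) for the block-probability parameters and
    ((K−1)/2)·log n for the mixing proportions.
    """
    n = a.shape[0]
    counts = np.bincount(labels, minlength=k).astype(float)
    z = np.zeros((n, k))
    z[np.arange(n), labels] = 1.0
    edges = z.T @ a @ z
    dyads = np.outer(counts, counts) - np.diag(counts)
    ll = 0.0
    for p in range(k):
        for q in range(p, k):
            d = dyads[p, q] if p != q else dyads[p, p] / 2
            e = edges[p, q] if p != q else edges[p, p] / 2
            if d <= 0:
                continue
            rate = np.clip(e / d, _EPS, 1 - _EPS)
            ll += e * np.log(rate) + (d - e) * np.log1p(-rate)
    nz = counts[counts > 0]
    ll += float(np.sum(nz * np.log(nz / n)))
    penalty = (k * (k + 1) / 4) * np.log(n * (n - 1) / 2) + ((k - 1) / 2) * np.log(n)
    return float(ll - penalty)


def fit_sbm(graph, k_range=range(1, 7), n_restarts: int = 5,
            seed: int = 0) -> BlockFit:
    """Fit the Bernoulli SBM and select K by ICL.

    Parameters
    ----------
    graph:
        networkx Graph (unsigned skeleton is taken) or 0/1 adjacency.
    k_range:
        Candidate block counts (within [1, 10]).
    n_restarts:
        Random restarts added to the spectral initialisation per K; the
        best-ELBO fit per K is kept, so more restarts never lower ICL.
    seed:
        Seeds the spectral k-means and random initialisations.
    """
    a, nodes = _as_adjacency(graph)
    n = a.shape[0]
    if n == 0:
        raise ValueError("cannot fit an SBM to an empty network")
    best = None
    icl_by_k: dict = {}
    for k in k_range:
        if not 1 <= k <= min(10, n):
            continue
        # restart r always uses the same generator, so adding restarts can
        # only improve the best-of-restarts fit (ICL is monotone in restarts)
        inits = [_spectral_tau(a, k, np.random.default_rng((seed, k, 0)))]
        for r in range(1, n_restarts + 1):
            rng_r = np.random.default_rng((seed, k, r))
            inits.append(_labels_to_tau(rng_r.integers(k, size=n), k))
        best_k = None
        for tau0 in inits:
            tau, prop, pi, elbo = _vem(a, tau0)
            if best_k is None or elbo > best_k[3]:
                best_k = (tau, prop, pi, elbo)
        tau, prop, pi, elbo = best_k
        labels = tau.argmax(axis=1)
        # re-index to occupied blocks only
        occupied, labels = np.unique(labels, return_inverse=True)
        k_eff = occupied.size
        icl = icl_score(a, labels, k_eff)
        icl_by_k[k] = icl
        if best is None or icl > best[0]:
            best = (icl, elbo, k_eff, labels)
    icl, elbo, k_eff, labels = best
    deg = a.sum(axis=1)
    order = np.argsort(
        [-deg[labels == b].mean() for b in range(k_eff)], kind="stable"
    )
    relabel = np.empty(k_eff, dtype=int)
    relabel[order] = np.arange(k_eff)
    labels = relabel[labels]
    z = np.zeros((n, k_eff))
    z[np.arange(n), labels] = 1.0
    counts = z.sum(axis=0)
    edges = z.T @ a @ z
    dyads = np.outer(counts, counts) - np.diag(counts)
    pi_hat = np.divide(edges, np.maximum(dyads, 1.0))
    mean_deg = np.array([deg[labels == b].mean() for b in range(k_eff)])
    se_deg = np.array([
        deg[labels == b].std(ddof=1) / np.sqrt((labels == b).sum())
        if (labels == b).sum() > 1 else np.nan
        for b in range(k_eff)
    ])
    within = np.array([
        (edges[b, b] / 2) / (counts[b] * (counts[b] - 1) / 2)
        if counts[b] >= 2 else np.nan
        for b in range(k_eff)
    ])
    roles = (
        {b: ROLE_NAMES[b] for b in range(3)} if k_eff == 3 else
        {b: f"block_{b}" for b in range(k_eff)}
    )
    return BlockFit(
        n_blocks=k_eff,
        memberships={node: int(b) for node, b in zip(nodes, labels)},
        pi=pi_hat,
        icl=icl,
        elbo=elbo,
        icl_by_k=icl_by_k,
        block_mean_degree=mean_deg,
        block_mean_degree_se=se_deg,
        within_connectance=within,
        roles=roles,
    )
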