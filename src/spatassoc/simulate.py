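"""Synthetic point-intercept surveys with known ground truth.

The generator emulates the sampling design the pipeline targets: plots of
``n_pinpoints`` point-intercept positions, per-plot species occupancy counts
drawn from a log-normal abundance law modulated by a 1-D environmental
niche, and *planted* pairwise interactions.  A planted pair (i, j, θ) places
species i uniformly, then draws j's pinpoints by weighted sampling without
replacement with weight exp(θ) on pinpoints i occupies — an exponential tilt
of the hypergeometric null that reduces *exactly* to it at θ = 0 (sequential
weighted sampling without replacement is realised by the Gumbel top-k trick,
which is uniform when all weights are equal).  Positive θ plants
aggregation, negative θ segregation.

Trait tables with group-structured syndromes and block-structured random
graphs are generated for the downstream trait and SBM stages.  Everything is
deterministic under the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .survey import PlotSurvey, SurveyCollection

__all__ = [
    "PlantedPair",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_survey",
    "generate_environment",
    "generate_traits",
    "generate_block_network",
]

TRAIT_NAMES = ("SLA", "LDMC", "leaf_area", "vegetative_height", "seed_mass")


@dataclass(frozen=True)
class PlantedPair:
    """A planted interaction: tilt strength θ between species i and j.

    ``theta_env_slope`` optionally modulates θ linearly along the
    environmental gradient, θ_s = θ + slope·(e_s − 0.5), emulating
    context-dependent associations that switch sign between plots.
    """

    species_i: int
    species_j: int
    theta: float
    plots: tuple | None = None  # None: every plot where both occur
    theta_env_slope: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of a synthetic survey.

    Defaults reflect the point-intercept protocol (300 pinpoints/plot) at a
    desk scale of 20 plots × 80 species; the abundance law (log-normal,
    median 18 contacts ≈ 6% of pinpoints, σ_log 0.55) gives the sparse sward
    occupancies under which the per-plot tests operate.
    """

    n_plots: int = 20
    n_pinpoints: int = 300
    n_species: int = 80
    abundance_median: float = 18.0
    abundance_sigma: float = 0.55
    niche_strength: float = 0.0   # 0: no gradient effect; 1: full Gaussian niche
    niche_breadth: float = 0.35
    planted: tuple = ()
    occupancy_prob: float = 1.0   # chance a species is present in a plot at all
    seed: int = 0

    def species_ids(self) -> list:
        return [f"sp{i:03d}" for i in range(self.n_species)]

    def plot_ids(self) -> list:
        return [f"P{i:02d}" for i in range(self.n_plots)]


@dataclass
class SyntheticTruth:
    """Planted structure to score recovery against."""

    planted: list                       # (species_i_id, species_j_id, theta, plots)
    margins: pd.DataFrame               # plot × species realized n_is
    gradient: pd.Series                 # plot -> environmental position in [0, 1]
    trait_groups: pd.Series | None = None
    block_memberships: np.ndarray | None = None


def _weighted_subset(n_points: int, size: int, log_w: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Weighted sampling of ``size`` points without replacement (Gumbel top-k)."""
    g = log_w + rng.gumbel(size=n_points)
    return np.argpartition(-g, size - 1)[:size] if size > 0 else np.array([], int)


def generate_survey(config: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> tuple:
    """Draw a survey collection and its ground truth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    species = config.species_ids()
    plot_ids = config.plot_ids()
    n_pin = config.n_pinpoints

    planted_by_species: dict = {}
    for pp in config.planted:
        for s in (pp.species_i, pp.species_j):
            if s in planted_by_species:
                raise ValueError(f"species index {s} appears in two planted pairs")
            if not 0 <= s < config.n_species:
                raise ValueError(f"planted species index {s} out of range")
            planted_by_species[s] = pp

    gradient = (np.linspace(0.0, 1.0, config.n_plots)
                if config.n_plots > 1 else np.array([0.5]))
    optima = rng.uniform(0.0, 1.0, size=config.n_species)

    # per-plot, per-species occupancy counts
    margins = np.zeros((config.n_plots, config.n_species), dtype=int)
    for p in range(config.n_plots):
        niche = np.exp(-((gradient[p] - optima) ** 2)
                       / (2 * config.niche_breadth**2))
        factor = (1 - config.niche_strength) + config.niche_strength * niche
        lam = config.abundance_median * factor
        counts = np.rint(
            lam * np.exp(rng.normal(0.0, config.abundance_sigma,
                                    size=config.n_species))
        ).astype(int)
        if config.occupancy_prob < 1.0:
            counts[rng.random(config.n_species) > config.occupancy_prob] = 0
        margins[p] = np.clip(counts, 0, n_pin)

    plots = []
    for p, plot_id in enumerate(plot_ids):
        occupancy: dict = {}
        # independent (non-planted) species and first members of planted pairs
        for s in range(config.n_species):
            n_s = margins[p, s]
            if n_s == 0:
                continue
            pp = planted_by_species.get(s)
            if pp is not None and s == pp.species_j:
                continue  # placed after its partner
            occupancy[species[s]] = frozenset(
                int(x) for x in rng.choice(n_pin, size=n_s, replace=False)
            )
        for pp in config.planted:
            j = pp.species_j
            n_j = margins[p, j]
            if n_j == 0:
                continue
            partner = occupancy.get(species[pp.species_i])
            active = pp.plots is None or plot_id in pp.plots
            theta = pp.theta + pp.theta_env_slope * (gradient[p] - 0.5)
            log_w = np.zeros(n_pin)
            if partner is not None and active and theta != 0.0:
                log_w[list(partner)] = theta
            occupancy[species[j]] = frozenset(
                int(x) for x in _weighted_subset(n_pin, n_j, log_w, rng)
            )
        if occupancy:
            plots.append(PlotSurvey(plot_id, n_pin, occupancy))

    truth = SyntheticTruth(
        planted=[
            (species[pp.species_i], species[pp.species_j], pp.theta,
             list(pp.plots) if pp.plots is not None else None)
            for pp in config.planted
        ],
        margins=pd.DataFrame(margins, index=plot_ids, columns=species),
        gradient=pd.Series(gradient, index=plot_ids, name="gradient"),
    )
    return SurveyCollection(plots), truth


def generate_environment(config: SyntheticConfig,
                         rng: np.random.Generator | None = None,
                         truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """Plot-level abiotic table driven by the same 1-D gradient.

    The gradient is read as elevation-like stress: pH and temperature
    variables fall along it, freezing degree days rise; small independent
    noise keeps the covariates from being perfectly collinear.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    plot_ids = config.plot_ids()
    e = (truth.gradient.to_numpy() if truth is not None
         else (np.linspace(0, 1, config.n_plots) if config.n_plots > 1
               else np.array([0.5])))
    n = len(plot_ids)
    noise = lambda s: rng.normal(0.0, s, size=n)  # noqa: E731
    env = pd.DataFrame({
        "pH": 6.5 - 2.0 * e + noise(0.45),
        "N_pct": np.clip(0.3 + 0.5 * e + noise(0.12), 0.01, None),
        "CN_ratio": 12 + 8 * e + noise(2.5),
        "organic_matter": np.clip(5 + 20 * e + noise(5.0), 0.1, None),
        "GDD": 2200 - 1600 * e + noise(280.0),
        "FDD": -(50 + 450 * e + noise(110.0)),
        "ETP": 650 - 250 * e + noise(90.0),
        "T_mean": 9.0 - 7.0 * e + noise(1.3),
        "T_min_coldest": -2.0 - 8.0 * e + noise(1.6),
        "precipitation": 900 + 500 * e + noise(160.0),
    }, index=pd.Index(plot_ids, name="plot_id"))
    return env


def generate_traits(n_per_group: dict, group_log_means: dict,
                    group_log_cov, seed: int = 0) -> tuple:
    """Log-normal trait syndromes per group.

    ``group_log_means`` maps group label -> length-5 mean vector on the log
    scale (order: SLA, LDMC, leaf_area, vegetative_height, seed_mass);
    ``group_log_cov`` is a shared 5×5 covariance (or a mapping per group).
    Returns (TraitTable DataFrame, group-label Series).
    """
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    counter = 0
    for group in sorted(n_per_group):
        n = n_per_group[group]
        mean = np.asarray(group_log_means[group], dtype=float)
        cov = np.asarray(
            group_log_cov[group] if isinstance(group_log_cov, dict)
            else group_log_cov, dtype=float)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("trait covariance must be positive-definite") from err
        draws = np.exp(rng.multivariate_normal(mean, cov, size=n,
                                               method="cholesky"))
        ids = [f"sp{counter + i:03d}" for i in range(n)]
        counter += n
        frames.append(pd.DataFrame(draws, index=ids, columns=TRAIT_NAMES))
        labels.extend((i, group) for i in ids)
    traits = pd.concat(frames)
    traits.index.name = "species_id"
    groups = pd.Series(dict(labels), name="group")
    groups.index.name = "species_id"
    return traits, groups


def generate_block_network(block_sizes, pi, seed: int = 0) -> tuple:
    """Undirected Bernoulli adjacency with planted block structure.

    Returns (adjacency, memberships).  ``pi`` must be symmetric with entries
    in [0, 1]; no self-loops are drawn.
    """
    pi = np.asarray(pi, dtype=float)
    if not np.allclose(pi, pi.T) or pi.min() < 0 or pi.max() > 1:
        raise ValueError("pi must be symmetric with entries in [0, 1]")
    sizes = np.asarray(block_sizes, dtype=int)
    z = np.repeat(np.arange(sizes.size), sizes)
    n = z.size
    rng = np.random.default_rng(seed)
    a = np.zeros((n, n), dtype=np.int8)
    rows, cols = np.triu_indices(n, k=1)
    p_edge = pi[z[rows], z[cols]]
    edges = rng.random(rows.size) < p_edge
    a[rows[edges], cols[edges]] = 1
    return a | a.T, z


def null_config(**overrides) -> SyntheticConfig:
    """Convenience: a fully null configuration (no planted structure)."""
    return replace(SyntheticConfig(), planted=(), **overrides)
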