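"""End-to-end orchestration: local tests → combination → screening →
network → SBM → traits/environment, with TSV/JSON outputs and a manifest.

The in-memory entry points (:func:`pair_tests`, :func:`run_association`,
:func:`local_association_counts`) are what the test-suite and simulations
call; :func:`run_pipeline` wires them to a run directory for the CLI.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import sbm as sbm_mod
from .combine import combine_pvalues
from .local_tests import hypergeom_pvalues_batch, pvalue_support
from .network import build_network, er_null_tests, group_abundance_models
from .screening import call_regional, discrete_fdr_plots, prefilter_pairs
from .survey import (
    SurveyCollection,
    cooccurring_pairs,
    read_environment_table,
    read_survey,
    read_trait_table,
    write_survey,
)
from .traits_env import (
    association_richness_model,
    functional_rarity,
    pairwise_permanova,
    trait_pca,
)

__all__ = [
    "RunConfig",
    "pair_tests",
    "run_association",
    "local_association_counts",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Run-level knobs; thresholds the protocol fixes are defaults here."""

    alpha: float = 0.05
    combine_variant: str = "gamma2"   # gamma2 | gamma3 | exact
    exact_cap: int = 1_000_000
    null_replicates: int = 999
    sbm_k_max: int = 6
    sbm_restarts: int = 5
    seed: int = 0
    survey: str | None = None
    manifest: str | None = None
    environment: str | None = None
    traits: str | None = None
    out_dir: str = "run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def pair_tests(collection: SurveyCollection) -> pd.DataFrame:
    """Exact one-tailed tests for every co-occurring pair in every shared plot.

    Returns a tidy frame with one row per (pair, plot):
    species_i, species_j, plot_id, n_ij, n_i, n_j, n_pinpoints, p_plus, p_minus.
    """
    rows = []
    for plot in collection.plots:
        species = sorted(plot.occupancy)
        for a, b in itertools.combinations(species, 2):
            rows.append((a, b, plot.plot_id, plot.colocation(a, b),
                         plot.count(a), plot.count(b), plot.n_pinpoints))
    if not rows:
        return pd.DataFrame(columns=[
            "species_i", "species_j", "plot_id", "n_ij", "n_i", "n_j",
            "n_pinpoints", "p_plus", "p_minus"])
    df = pd.DataFrame(rows, columns=[
        "species_i", "species_j", "plot_id", "n_ij", "n_i", "n_j",
        "n_pinpoints"])
    p_plus, p_minus = hypergeom_pvalues_batch(
        df["n_ij"], df["n_i"], df["n_j"], df["n_pinpoints"])
    df["p_plus"], df["p_minus"] = p_plus, p_minus
    return df


def _pair_structures(tests: pd.DataFrame) -> tuple:
    """Margins and per-tail (pvalues, supports) per pair, from the test table."""
    margins: dict = {}
    pvals: dict = {}
    for (si, sj), sub in tests.groupby(["species_i", "species_j"], sort=True):
        key = (si, sj)
        margins[key] = list(zip(sub["n_i"], sub["n_j"], sub["n_pinpoints"]))
        sup_plus = [pvalue_support(ni, nj, npin, "plus")
                    for ni, nj, npin in margins[key]]
        sup_minus = [pvalue_support(ni, nj, npin, "minus")
                     for ni, nj, npin in margins[key]]
        pvals[key] = {
            "plus": (sub["p_plus"].tolist(), sup_plus),
            "minus": (sub["p_minus"].tolist(), sup_minus),
        }
    return margins, pvals


def run_association(collection: SurveyCollection, alpha: float = 0.05,
                    variant: str = "gamma2") -> dict:
    """Local tests, pre-filter, combination and regional calls in one pass."""
    tests = pair_tests(collection)
    if tests.empty:
        return {"tests": tests, "associations": [], "tested_plus": set(),
                "tested_minus": set(), "margins": {}, "pair_pvalues": {}}
    margins, pair_pvalues = _pair_structures(tests)
    tested_plus, tested_minus = prefilter_pairs(margins, alpha, variant)
    combined: dict = {}
    for pair in set(tested_plus) | set(tested_minus):
        combined[pair] = {}
        for tail, tested in (("plus", tested_plus), ("minus", tested_minus)):
            if pair in tested:
                pv, sup = pair_pvalues[pair][tail]
                combined[pair][tail] = combine_pvalues(pv, sup, variant=variant)
    associations = call_regional(combined, tested_plus, tested_minus, alpha)
    return {
        "tests": tests,
        "associations": associations,
        "tested_plus": tested_plus,
        "tested_minus": tested_minus,
        "margins": margins,
        "pair_pvalues": pair_pvalues,
    }


def attribute_plots(result: dict, alpha: float = 0.05) -> None:
    """Post-hoc discrete-FDR attribution of contributing plots.

    Fills ``contributing_plots_plus`` / ``_minus`` on every regionally
    significant association in ``result`` (in place); calling it for a
    non-significant pair is a contract error, so only significant tails are
    visited.
    """
    tests = result["tests"]
    by_pair = dict(tuple(tests.groupby(["species_i", "species_j"], sort=False)))
    for assoc in result["associations"]:
        sub = by_pair.get(assoc.pair)
        if sub is None:
            continue
        for tail, flag in (("plus", assoc.significant_plus),
                           ("minus", assoc.significant_minus)):
            if not flag:
                continue
            pv, sup = result["pair_pvalues"][assoc.pair][tail]
            plots = discrete_fdr_plots(sub["plot_id"].tolist(), pv, sup, alpha)
            if tail == "plus":
                assoc.contributing_plots_plus = plots
            else:
                assoc.contributing_plots_minus = plots


def local_association_counts(result: dict, plot_ids: list,
                             alpha: float = 0.05) -> pd.Series:
    """Per-plot count of locally significant associations (n_asso).

    A plot counts one association for every significant pair whose
    discrete-FDR attribution includes it, in either tail.
    """
    attribute_plots(result, alpha)
    counts = pd.Series(0, index=pd.Index(plot_ids, name="plot_id"))
    for assoc in result["associations"]:
        for plots in (assoc.contributing_plots_plus,
                      assoc.contributing_plots_minus):
            for p in plots:
                if p in counts.index:
                    counts[p] += 1
    return counts.rename("n_asso")


def _association_frame(associations: list) -> pd.DataFrame:
    rows = []
    for a in associations:
        rows.append({
            "species_i": a.species_i, "species_j": a.species_j,
            "sign": a.sign, "p_plus": a.p_plus, "p_minus": a.p_minus,
            "q_plus": a.q_plus, "q_minus": a.q_minus,
            "tested_plus": a.tested_plus, "tested_minus": a.tested_minus,
            "contributing_plots": ";".join(sorted(
                set(a.contributing_plots_plus) | set(a.contributing_plots_minus))),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write TSV/JSON artefacts to the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"alpha": config.alpha, "variant": config.combine_variant,
                      "seed": config.seed}

    collection = read_survey(config.survey, config.manifest)
    write_survey(collection, out / "survey_collapsed.tsv")
    co = cooccurring_pairs(collection)
    manifest["n_plots"] = len(collection.plots)
    manifest["n_species"] = len(collection.species_index)
    manifest["n_cooccurring_pairs"] = len(co)

    result = run_association(collection, config.alpha, config.combine_variant)
    result["tests"].to_csv(out / "pair_plot_tests.tsv", sep="\t", index=False)
    attribute_plots(result, config.alpha)
    assoc_df = _association_frame(result["associations"])
    assoc_df.to_csv(out / "associations.tsv", sep="\t", index=False)
    manifest["tested_plus"] = len(result["tested_plus"])
    manifest["tested_minus"] = len(result["tested_minus"])
    manifest["excluded_plus"] = len(co) - len(result["tested_plus"])
    manifest["excluded_minus"] = len(co) - len(result["tested_minus"])
    sig = [a for a in result["associations"] if a.sign != "none"]
    manifest["significant_plus"] = sum(a.significant_plus for a in sig)
    manifest["significant_minus"] = sum(a.significant_minus for a in sig)
    manifest["sign_both"] = sum(a.sign == "both" for a in sig)

    net = build_network(result["associations"], co)
    manifest["n_nodes"] = net.n_nodes
    manifest["n_edges"] = net.n_edges
    manifest["connectance"] = net.connectance
    manifest["connectance_associated"] = net.connectance_associated
    manifest["clustering"] = net.clustering
    edge_rows = [(u, v, d["sign"]) for u, v, d in net.graph.edges(data=True)]
    pd.DataFrame(edge_rows, columns=["species_i", "species_j", "sign"]).to_csv(
        out / "network_edges.tsv", sep="\t", index=False)

    block_fit = None
    if net.n_edges >= 1:
        nulls = er_null_tests(net, config.null_replicates, config.seed,
                              config.alpha)
        manifest["p_clustering"] = nulls["p_clustering"]
        manifest["n_hubs"] = len(nulls["hubs"])
        block_fit = sbm_mod.fit_sbm(
            net.graph, range(1, config.sbm_k_max + 1),
            config.sbm_restarts, config.seed)
        manifest["sbm_k"] = block_fit.n_blocks
        pd.DataFrame({
            "species_id": list(block_fit.memberships),
            "block": list(block_fit.memberships.values()),
            "role": [block_fit.roles[b]
                     for b in block_fit.memberships.values()],
        }).to_csv(out / "blocks.tsv", sep="\t", index=False)

    environment = (read_environment_table(config.environment)
                   if config.environment else None)
    traits = read_trait_table(config.traits) if config.traits else None

    if environment is not None:
        abundance = collection.abundance_matrix()
        environment = environment.join(collection.n_individuals(), how="left")
        n_asso = local_association_counts(result, collection.plot_ids,
                                          config.alpha)
        # precipitation tracks freezing degree days; keep FDD of the two
        abiotic = [c for c in ("pH", "N_pct", "CN_ratio", "GDD", "FDD", "ETP")
                   if c in environment.columns]
        try:
            model = association_richness_model(n_asso, environment,
                                               abiotic=abiotic)
            model.coefficients.to_csv(out / "richness_model.tsv", sep="\t")
            manifest["richness_r2_baseline"] = model.r2_baseline
            manifest["richness_r2_full"] = model.r2_full
        except ValueError as err:
            warnings.warn(f"association-richness model skipped: {err}")
        if block_fit is not None:
            try:
                gm = group_abundance_models(block_fit.memberships, abundance,
                                            environment, covariates=abiotic)
                gm.to_csv(out / "group_models.tsv", sep="\t")
            except ValueError as err:
                warnings.warn(f"group abundance models skipped: {err}")
    else:
        warnings.warn("no environment table: abiotic stages skipped")

    if traits is not None and block_fit is not None:
        trait_cols = [c for c in traits.columns if c in
                      ("SLA", "LDMC", "leaf_area", "vegetative_height",
                       "seed_mass")]
        pca = trait_pca(traits[trait_cols])
        groups = pd.Series(block_fit.memberships, name="block")
        common = pca["scores"].index.intersection(groups.index)
        if len(common) >= 4:
            perm = pairwise_permanova(pca["scores"].loc[common],
                                      groups.loc[common], seed=config.seed)
            perm.to_csv(out / "permanova.tsv", sep="\t", index=False)
        rar = functional_rarity(traits[trait_cols],
                                collection.abundance_matrix())
        rar["per_species"].to_csv(out / "functional_rarity.tsv", sep="\t")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    return out
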