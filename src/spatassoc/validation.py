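"""Simulation-based validation of the pipeline's statistical guarantees.

Each function recomputes one guarantee from scratch on synthetic data with
planted ground truth and returns the measured quantities: agreement of the
gamma combination with the exact stratified null, type-I validity of the
combined test, false-discovery control of the screening stage, power and
sign recovery on planted interactions, soundness of the detectability
pre-filter, block-recovery of the SBM, calibration of the Erdős–Rényi
clustering test, and parameter recovery of the association-richness GLM.

The problem sizes are desk-scale study conditions (documented in the
methods note); every function is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .combine import combine_exact, combine_gamma
from .local_tests import pvalue_support
from .network import _er_adjacency, _transitivity, er_null_ensemble
from .pipeline import _pair_structures, pair_tests, run_association
from .sbm import fit_sbm
from .screening import bh_adjust, prefilter_pairs
from .simulate import PlantedPair, SyntheticConfig, generate_block_network, \
    generate_survey
from .traits_env import association_richness_model

__all__ = [
    "gamma_exact_agreement",
    "combined_test_type_one_error",
    "screening_fdr",
    "planted_pair_recovery",
    "prefilter_soundness",
    "sbm_block_recovery",
    "clustering_null_calibration",
    "richness_glm_recovery",
]


def _brute_force_combined(pvalues, supports, t_obs=None):
    """Independent oracle: full enumeration of the joint outcome space."""
    if t_obs is None:
        t_obs = float(np.sum(-np.log(pvalues)))
    grids = [-np.log(s.values) for s in supports]
    masses = [s.masses for s in supports]
    t = np.array([0.0])
    m = np.array([1.0])
    for g, w in zip(grids, masses):
        t = np.add.outer(t, g).ravel()
        m = np.multiply.outer(m, w).ravel()
    tol = 1e-9 * max(1.0, abs(t_obs))
    return float(m[t >= t_obs - tol].sum())


def gamma_exact_agreement(seed: int = 0, n_configs: int = 200) -> dict:
    """Exactness of the convolution and closeness of the gamma tail.

    Random pair/plot configurations with up to 3 plots and at most 40
    pinpoints; the observed co-location counts are drawn from the null.
    Reports the worst absolute deviation of the exact convolution from full
    enumeration, and the worst |log10| ratio of gamma2 vs. exact wherever
    the exact p-value lies in [1e-5, 0.5] (gamma3's median closeness is
    reported alongside).
    """
    rng = np.random.default_rng(seed)
    max_exact_err = 0.0
    log_ratios_g2, log_ratios_g3 = [], []
    for _ in range(n_configs):
        k_plots = int(rng.integers(1, 4))
        n_pin = int(rng.integers(8, 41))
        pvalues, supports = [], []
        tail = "plus" if rng.random() < 0.5 else "minus"
        for _ in range(k_plots):
            n_i = int(rng.integers(1, n_pin // 2 + 1))
            n_j = int(rng.integers(1, n_pin // 2 + 1))
            sup = pvalue_support(n_i, n_j, n_pin, tail)
            obs = rng.choice(sup.values.size, p=sup.masses)
            pvalues.append(float(sup.values[obs]))
            supports.append(sup)
        p_exact = combine_exact(pvalues, supports)
        p_bf = _brute_force_combined(pvalues, supports)
        max_exact_err = max(max_exact_err, abs(p_exact - p_bf))
        if 1e-5 <= p_exact <= 0.5:
            p_g2 = combine_gamma(pvalues, supports, "gamma2")
            p_g3 = combine_gamma(pvalues, supports, "gamma3")
            log_ratios_g2.append(abs(np.log10(p_g2 / p_exact)))
            log_ratios_g3.append(abs(np.log10(p_g3 / p_exact)))
    return {
        "max_exact_abs_error": max_exact_err,
        "max_log10_ratio_gamma2": float(np.max(log_ratios_g2)),
        "median_log10_ratio_gamma2": float(np.median(log_ratios_g2)),
        "median_log10_ratio_gamma3": float(np.median(log_ratios_g3)),
        "n_compared": len(log_ratios_g2),
    }


def combined_test_type_one_error(seed: int = 0, n_pairs: int = 10_000,
                                 alphas=(0.01, 0.05)) -> dict:
    """Empirical P(p_combined <= α) on fully null surveys, exact method.

    Many independent surveys of 3 plots × 8 species with no planted
    interactions supply null species pairs (K = 3 strata each); rejection
    rates must not exceed α + 2·MC-SE in either tail.
    """
    p_by_tail = {"plus": [], "minus": []}
    sub = 0
    while len(p_by_tail["plus"]) < n_pairs:
        cfg = SyntheticConfig(n_plots=3, n_species=8, abundance_median=15,
                              abundance_sigma=0.4, seed=seed * 1009 + sub)
        sub += 1
        coll, _ = generate_survey(cfg)
        _, pvals = _pair_structures(pair_tests(coll))
        for pair in sorted(pvals):
            for tail in ("plus", "minus"):
                pv, sup = pvals[pair][tail]
                p_by_tail[tail].append(combine_exact(pv, sup))
    out = {"n_pairs": n_pairs}
    for tail in ("plus", "minus"):
        p = np.array(p_by_tail[tail][:n_pairs])
        for a in alphas:
            out[f"rate_{tail}_alpha_{a}"] = float((p <= a).mean())
            out[f"bound_alpha_{a}"] = a + 2 * np.sqrt(a * (1 - a) / n_pairs)
    return out


def _mixture_config(seed: int) -> tuple:
    planted = tuple(
        PlantedPair(2 * k, 2 * k + 1, 3.0 if k % 2 == 0 else -3.0)
        for k in range(6)
    )
    cfg = SyntheticConfig(n_plots=5, n_species=12, abundance_median=25,
                          abundance_sigma=0.35, planted=planted, seed=seed)
    return cfg, planted


def screening_fdr(seed: int = 0, n_replicates: int = 500,
                  alpha: float = 0.05) -> dict:
    """Empirical FDR of the full screening stage on a null/planted mixture.

    Each replicate plants 6 interacting pairs among 12 species (≈ 10% of
    the 66 pairs; the rest are null) over 5 plots; a discovery is false when
    the pair was not planted or its sign contradicts the planted tilt.
    Reports mean false-discovery proportion and its Monte-Carlo SE.
    """
    fdp = np.empty(n_replicates)
    sens = np.empty(n_replicates)
    for rep in range(n_replicates):
        cfg, planted = _mixture_config(seed * 70001 + rep)
        coll, truth = generate_survey(cfg)
        res = run_association(coll, alpha=alpha, variant="gamma2")
        want = {}
        for i, j, th, _ in truth.planted:
            key = (i, j) if i < j else (j, i)
            want[key] = "positive" if th > 0 else "negative"
        disc = [(a.pair, a.sign) for a in res["associations"] if a.sign != "none"]
        false = sum(1 for pair, sign in disc
                    if pair not in want
                    or sign not in (want[pair], "both"))
        fdp[rep] = false / max(len(disc), 1)
        sens[rep] = sum(1 for pair, sign in disc if pair in want) / len(want)
    return {
        "empirical_fdr": float(fdp.mean()),
        "mc_se": float(fdp.std(ddof=1) / np.sqrt(n_replicates)),
        "mean_sensitivity": float(sens.mean()),
        "n_replicates": n_replicates,
    }


def planted_pair_recovery(seed: int = 0, n_replicates: int = 50,
                          alpha: float = 0.05) -> dict:
    """Power and sign accuracy for planted θ = ±3 interactions.

    20 plots, species occupying ≈ 30 of 300 pinpoints; 3 aggregating and 3
    segregating pairs per replicate.  Sensitivity is the fraction of planted
    pairs regionally detected; sign accuracy the fraction of detections
    whose sign matches the planted tilt.
    """
    planted = tuple(
        PlantedPair(2 * k, 2 * k + 1, 3.0 if k < 3 else -3.0)
        for k in range(6)
    )
    detected = correct = total = 0
    for rep in range(n_replicates):
        cfg = SyntheticConfig(n_plots=20, n_species=20, abundance_median=30,
                              abundance_sigma=0.25, planted=planted,
                              seed=seed * 90001 + rep)
        coll, truth = generate_survey(cfg)
        res = run_association(coll, alpha=alpha, variant="gamma2")
        sig = {a.pair: a.sign for a in res["associations"] if a.sign != "none"}
        for i, j, th, _ in truth.planted:
            key = (i, j) if i < j else (j, i)
            total += 1
            if key in sig:
                detected += 1
                correct += sig[key] == ("positive" if th > 0 else "negative")
    return {
        "sensitivity": detected / total,
        "sign_accuracy": correct / max(detected, 1),
        "n_planted": total,
    }


def prefilter_soundness(seed: int = 0, n_configs: int = 1000,
                        alpha: float = 0.05) -> dict:
    """No pair excluded by the detectability pre-filter can ever reach q <= α.

    For each random configuration of pair margins: (i) analytically, the
    BH-adjusted minimum combined p-value of every excluded pair must be
    >= α even in the most favourable dataset (all pairs at their minima —
    BH-adjusted values are coordinate-wise monotone, so this bounds every
    dataset); (ii) empirically, random draws of attainable p-values never
    push an excluded pair below α after BH over all pairs.
    """
    rng = np.random.default_rng(seed)
    violations = 0
    n_excluded = 0
    for _ in range(n_configs):
        n_pairs = int(rng.integers(4, 9))
        margins = {}
        for idx in range(n_pairs):
            k_plots = int(rng.integers(1, 4))
            margins[("a", f"p{idx}")] = [
                (int(rng.integers(1, 61)), int(rng.integers(1, 61)), 300)
                for _ in range(k_plots)
            ]
        tested_plus, tested_minus = prefilter_pairs(margins, alpha, "gamma2")
        for tail, tested in (("plus", tested_plus), ("minus", tested_minus)):
            excluded = [p for p in margins if p not in tested]
            if not excluded:
                continue
            n_excluded += len(excluded)
            pairs = sorted(margins)
            supports = {
                p: [pvalue_support(ni, nj, npin, tail)
                    for ni, nj, npin in margins[p]]
                for p in pairs
            }
            p_min = np.array([
                combine_gamma([s.min_p for s in supports[p]], supports[p])
                for p in pairs
            ])
            q_min = bh_adjust(p_min)
            violations += sum(
                1 for p, q in zip(pairs, q_min) if p in excluded and q < alpha
            )
            # random attainable observations can only raise adjusted values
            obs = np.array([
                combine_gamma(
                    [float(s.values[rng.choice(s.values.size, p=s.masses)])
                     for s in supports[p]],
                    supports[p])
                for p in pairs
            ])
            q_obs = bh_adjust(np.maximum(obs, p_min))
            violations += sum(
                1 for p, q in zip(pairs, q_obs) if p in excluded and q <= alpha
            )
    return {"n_configs": n_configs, "n_excluded_checked": n_excluded,
            "violations": violations}


def sbm_block_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Membership recovery on planted two-block graphs and parsimony on ER.

    Planted Π = [[0.75, 0.30], [0.30, 0.02]] with 30 + 30 nodes must be
    recovered with ARI >= 0.9; Erdős–Rényi graphs of matched size/density
    should select K = 1.
    """
    pi = [[0.75, 0.30], [0.30, 0.02]]
    ari_ok = 0
    k1 = 0
    for s in range(n_seeds):
        a, z = generate_block_network([30, 30], pi, seed=seed * 31 + s)
        fit = fit_sbm(a, range(1, 5), n_restarts=3, seed=seed * 31 + s)
        labels = np.array([fit.memberships[i] for i in range(60)])
        ari_ok += adjusted_rand_score(z, labels) >= 0.9
        rng = np.random.default_rng(seed * 57 + s)
        er = _er_adjacency(60, 160, rng)
        fit_er = fit_sbm(er, range(1, 5), n_restarts=2, seed=seed * 57 + s)
        k1 += fit_er.n_blocks == 1
    return {
        "ari_pass_rate": ari_ok / n_seeds,
        "er_k1_rate": k1 / n_seeds,
        "n_seeds": n_seeds,
    }


def clustering_null_calibration(seed: int = 0, n_runs: int = 200,
                                n_nodes: int = 60, n_edges: int = 150,
                                n_replicates: int = 199,
                                alpha: float = 0.05) -> dict:
    """Call rate of the ER clustering test when the data *are* ER."""
    rng = np.random.default_rng(seed)
    calls = 0
    for run in range(n_runs):
        obs = _transitivity(_er_adjacency(n_nodes, n_edges, rng))
        ens = er_null_ensemble(n_nodes, n_edges, n_replicates,
                               seed=seed * 131 + run)
        p = (1 + np.sum(ens.clustering >= obs - 1e-12)) / (n_replicates + 1)
        calls += p <= alpha
    return {"call_rate": calls / n_runs, "n_runs": n_runs}


def richness_glm_recovery(seed: int = 0, n_plots: int = 120) -> dict:
    """Sign recovery and exact partition accounting of the abiotic GLM.

    Per-plot association counts are generated with a log link: positive
    individual-count effect, negative pH effect, positive nitrogen effect,
    with gamma-mixed overdispersion; the fitted quasi-Poisson model must
    recover the signs and the hierarchical partition must sum to the
    full-model adjusted R².
    """
    rng = np.random.default_rng(seed)
    env = pd.DataFrame({
        "n_individuals": rng.integers(200, 800, n_plots).astype(float),
        "pH": rng.normal(5.5, 0.8, n_plots),
        "N_pct": rng.normal(0.6, 0.15, n_plots),
        "ETP": rng.normal(500, 60, n_plots),
    }, index=[f"P{i:03d}" for i in range(n_plots)])
    eta = (1.0 + 0.002 * env["n_individuals"] - 0.7 * (env["pH"] - 5.5)
           + 2.5 * (env["N_pct"] - 0.6))
    lam = np.exp(eta) * rng.gamma(5.0, 1 / 5.0, n_plots)
    y = pd.Series(rng.poisson(lam), index=env.index, name="n_asso")
    model = association_richness_model(y, env, abiotic=["pH", "N_pct", "ETP"])
    coef = model.coefficients["coefficient"]
    return {
        "ph_coefficient": float(coef.get("pH", np.nan)),
        "n_pct_coefficient": float(coef.get("N_pct", np.nan)),
        "signs_correct": float(coef.get("pH", 0) < 0 < coef.get("N_pct", 0)),
        "r2_baseline": model.r2_baseline,
        "r2_full": model.r2_full,
        "partition_sum_error": float(
            abs(model.partition_shares.sum() - model.r2_full)),
    }
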