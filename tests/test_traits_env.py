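"""Trait-space, functional rarity and abiotic-model analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from spatassoc.simulate import generate_traits
from spatassoc.traits_env import (
    association_richness_model,
    functional_rarity,
    group_contrasts,
    hierarchical_partition,
    pairwise_permanova,
    trait_pca,
)


class TestTraitPca:
    def test_variance_fractions_sum_to_one(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 5)),
                         columns=list("abcde"))
        out = trait_pca(x)
        assert out["variance_fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_correlated_pair_dominates_first_axis(self, rng):
        base = rng.normal(size=40)
        x = pd.DataFrame({
            "t1": base, "t2": base + rng.normal(0, 0.05, 40),
            "t3": rng.normal(size=40), "t4": rng.normal(size=40),
        })
        out = trait_pca(x)
        load = out["loadings"]["PC1"].abs()
        assert load["t1"] > load["t3"] and load["t2"] > load["t4"]

    def test_constant_column_is_named_in_error(self, rng):
        x = pd.DataFrame({"flat": np.ones(10),
                          "ok": rng.normal(size=10)})
        with pytest.raises(ValueError, match="flat"):
            trait_pca(x)

    def test_group_syndrome_displaces_centroid(self):
        log_cov = np.diag([0.05] * 5)
        means = {"core": [2.6, 6.2, 3.0, -2.0, 0.4],
                 "other": [3.0, 5.4, 4.0, -1.0, 0.7]}
        traits, groups = generate_traits({"core": 15, "other": 40}, means,
                                         log_cov, seed=3)
        out = trait_pca(np.log(traits))
        scores = out["scores"]
        sep = (scores[groups == "core"].mean()
               - scores[groups == "other"].mean()).abs()
        assert sep.iloc[0] > 1.0  # centroids separate along the leading axes


class TestPairwisePermanova:
    def test_separated_groups_reach_min_p(self, rng):
        a = rng.normal(0, 1, size=(15, 3))
        b = rng.normal(10, 1, size=(15, 3))
        pts = pd.DataFrame(np.vstack([a, b]),
                           index=[f"s{i}" for i in range(30)])
        groups = pd.Series(["g1"] * 15 + ["g2"] * 15, index=pts.index)
        out = pairwise_permanova(pts, groups, n_perm=199, seed=0)
        assert out.loc[0, "p_value"] == pytest.approx(1 / 200)

    def test_singleton_group_skipped_with_warning(self, rng):
        pts = pd.DataFrame(rng.normal(size=(7, 2)),
                           index=[f"s{i}" for i in range(7)])
        groups = pd.Series(["g1"] * 6 + ["g2"], index=pts.index)
        with pytest.warns(UserWarning):
            out = pairwise_permanova(pts, groups, n_perm=99, seed=0)
        assert out.empty

    def test_null_rejection_rate_near_alpha(self, rng):
        hits = 0
        reps = 40
        for r in range(reps):
            pts = pd.DataFrame(rng.normal(size=(20, 2)),
                               index=[f"s{i}" for i in range(20)])
            groups = pd.Series(["g1"] * 10 + ["g2"] * 10, index=pts.index)
            out = pairwise_permanova(pts, groups, n_perm=99, seed=r)
            hits += out.loc[0, "p_value"] <= 0.05
        assert hits / reps <= 0.15  # ~alpha with MC slack


class TestFunctionalRarity:
    def test_scarcity_closed_form(self):
        traits = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        ab = pd.DataFrame({"a": [5], "b": [5]}, index=["P1"])
        out = functional_rarity(traits, ab)["per_plot"]
        # two species, equal share: S = exp(-2 ln2 * 0.5) = 0.5
        assert np.allclose(out["scarcity"], 0.5)

    def test_distinctiveness_hand_computed(self):
        d = pd.DataFrame([[0.0, 0.5, 0.5], [0.5, 0.0, 0.0], [0.5, 0.0, 0.0]],
                         index=list("abc"), columns=list("abc"))
        traits = pd.DataFrame({"x": [0.0, 1.0, 1.0]}, index=list("abc"))
        ab = pd.DataFrame({"a": [1], "b": [1], "c": [1]}, index=["P1"])
        out = functional_rarity(traits, ab, distances=d)["per_plot"]
        vals = out.set_index("species_id")["distinctiveness"]
        assert vals["a"] == pytest.approx(0.5)
        assert vals["b"] == pytest.approx(0.25)

    def test_identical_species_have_zero_distinctiveness(self):
        traits = pd.DataFrame({"x": [3.0, 3.0, 3.0]}, index=list("abc"))
        ab = pd.DataFrame({"a": [2], "b": [2], "c": [2]}, index=["P1"])
        out = functional_rarity(traits, ab)["per_plot"]
        assert np.allclose(out["distinctiveness"], 0.0)

    def test_lone_species_distinctiveness_undefined(self):
        traits = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        ab = pd.DataFrame({"a": [3], "b": [0]}, index=["P1"])
        with pytest.warns(UserWarning):
            out = functional_rarity(traits, ab)["per_plot"]
        assert np.isnan(out.loc[0, "distinctiveness"])

    def test_invariant_to_zero_abundance_species(self):
        traits = pd.DataFrame({"x": [1.0, 2.0, 9.0]}, index=list("abc"))
        ab_with = pd.DataFrame({"a": [4, 2], "b": [4, 2], "c": [0, 3]},
                               index=["P1", "P2"])
        full = functional_rarity(traits, ab_with)["per_plot"]
        p1 = full[full.plot_id == "P1"].set_index("species_id")
        # within P1, c is absent: a and b see only each other
        d_ab = abs(1.0 - 2.0)  # after z-scoring both have the same |diff|
        assert p1.loc["a", "distinctiveness"] == p1.loc["b", "distinctiveness"]


class TestGroupContrasts:
    def test_wilcoxon_matches_exact_enumeration(self):
        a = [1.2, 3.4, 2.2]
        b = [5.5, 6.1, 4.9, 7.0]
        # exact two-sided p by enumerating all C(7,3) group assignments
        pooled = a + b
        obs = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        stats = []
        for combo in itertools.combinations(range(7), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(7) if i not in combo]
            stats.append(mannwhitneyu(ga, gb, alternative="two-sided",
                                      method="exact").statistic)
        u_obs = obs.statistic
        n1, n2 = 3, 4
        mid = n1 * n2 / 2
        exact_p = np.mean([abs(s - mid) >= abs(u_obs - mid) - 1e-12
                           for s in stats])
        out = group_contrasts(
            pd.Series(pooled), pd.Series(["a"] * 3 + ["b"] * 4))
        assert out.loc[0, "p_value"] == pytest.approx(exact_p, abs=1e-9)

    def test_three_groups_add_kruskal_row(self, rng):
        vals = pd.Series(rng.normal(size=18))
        groups = pd.Series(["x", "y", "z"] * 6)
        out = group_contrasts(vals, groups)
        assert (out["test"] == "kruskal").sum() == 1
        assert (out["test"] == "wilcoxon").sum() == 3


class TestHierarchicalPartition:
    def test_orthogonal_predictors_share_marginals(self):
        r2 = {frozenset(): 0.0, frozenset({"a"}): 0.3, frozenset({"b"}): 0.1,
              frozenset({"a", "b"}): 0.4}
        shares = hierarchical_partition(
            lambda s: r2[frozenset(s)], ["a", "b"])
        assert shares["a"] == pytest.approx(0.3, abs=1e-12)
        assert shares["b"] == pytest.approx(0.1, abs=1e-12)

    def test_single_predictor_gets_everything(self):
        shares = hierarchical_partition(lambda s: 0.42 if s else 0.0, ["a"])
        assert shares["a"] == pytest.approx(0.42)

    def test_duplicated_predictor_splits_equally(self):
        def r2(subset):
            return 0.5 if subset else 0.0  # either copy explains everything
        shares = hierarchical_partition(r2, ["a", "a_copy"])
        assert shares["a"] == pytest.approx(shares["a_copy"], abs=1e-12)
        assert shares.sum() == pytest.approx(0.5, abs=1e-12)

    def test_capacity_limit(self):
        with pytest.raises(ValueError):
            hierarchical_partition(lambda s: 0.0, list("abcdefghi"))


class TestRichnessModel:
    def _env(self, rng, n=90):
        return pd.DataFrame({
            "n_individuals": rng.integers(200, 700, n).astype(float),
            "pH": rng.normal(5.5, 0.8, n),
            "N_pct": rng.normal(0.6, 0.15, n),
            "ETP": rng.normal(500, 60, n),
        }, index=[f"P{i:03d}" for i in range(n)])

    def test_effect_signs_recovered(self, rng):
        env = self._env(rng)
        eta = (1.0 + 0.002 * env["n_individuals"] - 0.7 * (env["pH"] - 5.5)
               + 2.5 * (env["N_pct"] - 0.6))
        y = pd.Series(rng.poisson(np.exp(eta)), index=env.index)
        m = association_richness_model(y, env, abiotic=["pH", "N_pct", "ETP"])
        assert m.coefficients.loc["pH", "coefficient"] < 0
        assert m.coefficients.loc["N_pct", "coefficient"] > 0
        assert m.r2_full > m.r2_baseline
        assert abs(m.partition_shares.sum() - m.r2_full) < 1e-9

    def test_null_stepwise_rarely_keeps_abiotic_terms(self, rng):
        kept = 0
        reps = 10
        for _ in range(reps):
            env = self._env(rng, n=60)
            eta = 1.0 + 0.002 * env["n_individuals"]
            y = pd.Series(rng.poisson(np.exp(eta)), index=env.index)
            m = association_richness_model(y, env,
                                           abiotic=["pH", "N_pct", "ETP"])
            kept += len(m.selected_terms) > 0
        # adjusted-R2 stepwise may keep a noise term occasionally, not usually
        assert kept <= reps // 2

    def test_zero_predictor_model_r2_zero(self, rng):
        env = self._env(rng, n=40)
        y = pd.Series(rng.poisson(5.0, 40), index=env.index)
        m = association_richness_model(y, env, abiotic=[], stepwise=False)
        # with only the individual count forced in, partition covers it all
        assert m.partition_shares.index.tolist() == ["n_individuals"]

    def test_collinear_predictors_rejected(self, rng):
        env = self._env(rng, n=50)
        env["FDD"] = env["ETP"] * -1.001 + rng.normal(0, 1e-6, 50)
        y = pd.Series(rng.poisson(5.0, 50), index=env.index)
        with pytest.raises(ValueError, match="collinear"):
            association_richness_model(y, env,
                                       abiotic=["pH", "ETP", "FDD"])

    def test_interaction_terms_enter_design(self, rng):
        env = self._env(rng, n=80)
        eta = (0.5 + 0.003 * env["n_individuals"]
               - 0.00002 * env["n_individuals"] * env["ETP"] + 0.01 * env["ETP"])
        y = pd.Series(rng.poisson(np.exp(eta)), index=env.index)
        m = association_richness_model(
            y, env, abiotic=["ETP"], interactions=["n_individuals:ETP"],
            stepwise=False)
        assert "n_individuals:ETP" in m.coefficients.index
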