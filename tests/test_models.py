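"""Phylogenetic signal, the two-part zero-inflated model and the
supporting comparative analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from comparonc.models import (
    HIGH_LEVERAGE_SPECIES,
    anchored_doubling_prediction,
    binary_pglmm,
    diet_model,
    fit_zero_inflated,
    inv_logit,
    logit,
    order_contrasts,
    partial_r2,
    phylo_paired_ttest,
    phylo_signal,
    predict_risk,
    recode_diet,
)
from comparonc.phylo import ModelFit, Phylogeny, SingularDesignError, gls_fit, lambda_transform
from comparonc.simulate import WorldSpec, simulate_species_traits, simulate_tree
from conftest import balanced_tree


def star_tree(n):
    tips = ",".join(f"t{i}:1" for i in range(n))
    return Phylogeny.from_newick(f"({tips});")


class TestPhyloSignal:
    def test_brownian_trait_detected(self):
        tree = balanced_tree(7)
        sp = sorted(tree.tip_labels)
        _, C1 = tree.covariance(1.0, species=sp)
        L = linalg.cholesky(C1 + 1e-10 * np.eye(128), lower=True)
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            res = phylo_signal(L @ r.standard_normal(128), C1)
            hits += res.pvalue < 0.05
        assert hits >= 18

    def test_no_signal_after_permutation(self):
        tree = balanced_tree(7)
        sp = sorted(tree.tip_labels)
        _, C1 = tree.covariance(1.0, species=sp)
        lams = []
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            lams.append(phylo_signal(r.standard_normal(128), C1).lam)
        assert np.median(lams) < 0.1

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            phylo_signal(np.array([1.0, 2.0, 3.0]), np.eye(3))

    def test_constant_trait_degenerate(self):
        assert phylo_signal(np.ones(6), np.eye(6)).degenerate


class TestBinaryPglmm:
    def test_s2_zero_matches_plain_logistic(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 50
        x = rng.standard_normal(n)
        y = (rng.random(n) < inv_logit(-0.3 + 1.2 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        tree = simulate_tree(n, seed=4)
        _, C1 = tree.covariance(1.0)
        fit = binary_pglmm(y, X, C1, s2=0.0)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.coef, ref.params, atol=1e-4)

    def test_slope_recovery_under_phylogenetic_random_effect(self):
        tree = simulate_tree(200, seed=9)
        sp = sorted(tree.tip_labels)
        _, C1 = tree.covariance(1.0, species=sp)
        Lc = linalg.cholesky(C1 + 1e-10 * np.eye(200), lower=True)
        ests = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = Lc @ r.standard_normal(200)  # log2-mass-like Brownian trait
            b = 0.5 * (Lc @ r.standard_normal(200))
            y = (r.random(200) < inv_logit(-0.5 + 1.0 * x + b)).astype(float)
            fit = binary_pglmm(y, np.column_stack([np.ones(200), x]), C1)
            ests.append(fit.coef[1])
        assert abs(np.mean(ests) - 1.0) <= 0.25

    def test_constant_response_flags_separation(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fit = binary_pglmm(np.ones(n), X, np.eye(n), s2=0.0)
        assert not fit.converged

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            binary_pglmm(np.array([0.0, 0.5, 1.0]), np.ones((3, 1)), np.eye(3))


def _manual_fit(coefs):
    names = ["intercept", "log_body_mass", "log_life_expectancy"]
    k = len(names)
    return ModelFit(
        names=names, coef=np.asarray(coefs, dtype=float), se=np.ones(k),
        tstat=np.zeros(k), pvalue=np.ones(k), lam=0.0, s2=None, loglik=0.0,
        n=10, df_resid=7, weights_desc="unit",
    )


class TestPredictRisk:
    def test_intercept_only_inverse_logit(self):
        fit = _manual_fit([-3.0, 0.0, 0.0])
        assert predict_risk(fit, 5.0, 12.0) == pytest.approx(4.7426, abs=1e-3)

    def test_doubling_shifts_linear_predictor_by_slope(self):
        b = -0.2
        fit = _manual_fit([-3.0, b, 0.0])
        p1 = predict_risk(fit, 8.0, 10.0)
        p2 = predict_risk(fit, 16.0, 10.0)
        lp1, lp2 = logit(p1 / 100), logit(p2 / 100)
        assert lp2 - lp1 == pytest.approx(b * np.log(2.0), abs=1e-12)

    def test_nonpositive_covariates_rejected(self):
        with pytest.raises(ValueError):
            predict_risk(_manual_fit([0, 0, 0]), -1.0, 5.0)

    def test_anchored_extrapolation_monotone(self):
        # decreasing anchors extrapolate to a lower value further out
        p10 = anchored_doubling_prediction(3.82, 3.71, 10)
        p11 = anchored_doubling_prediction(3.82, 3.71, 11)
        assert p11 < p10 < 3.71


class TestPartialR2:
    def _fits(self, b, rng, n=60):
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = b * x + rng.standard_normal(n)
        full = gls_fit(y, np.column_stack([np.ones(n), x]), np.eye(n),
                       names=["intercept", "x"])
        red = gls_fit(y, np.ones((n, 1)), np.eye(n), names=["intercept"])
        return full, red

    def test_reduced_equals_full_gives_zero(self, rng):
        full, _ = self._fits(1.0, rng)
        assert partial_r2(full, full) == 0.0

    def test_increases_with_effect_size(self, rng):
        vals = []
        for b in (0.3, 1.0, 3.0):
            r = np.random.default_rng(7)
            full, red = self._fits(b, r)
            vals.append(partial_r2(full, red))
        assert vals[0] < vals[1] < vals[2]
        assert 0 < vals[0] and vals[2] < 1

    def test_useless_predictor_near_zero(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 60
            x = r.standard_normal(n)
            z = r.standard_normal(n)
            y = x + r.standard_normal(n)
            full = gls_fit(y, np.column_stack([np.ones(n), x, z]), np.eye(n),
                           names=["intercept", "x", "z"])
            red = gls_fit(y, np.column_stack([np.ones(n), x]), np.eye(n),
                          names=["intercept", "x"])
            vals.append(partial_r2(full, red))
        assert np.median(vals) < 0.02

    def test_non_nested_rejected(self, rng):
        full, _ = self._fits(1.0, rng)
        other = gls_fit(rng.standard_normal(30), np.ones((30, 1)), np.eye(30))
        with pytest.raises(ValueError):
            partial_r2(full, other)


class TestPairedTtest:
    def test_star_tree_matches_classical_paired_t(self, rng):
        n = 14
        tree = star_tree(n)
        sp = tree.tip_labels
        a = rng.standard_normal(n) + 0.3
        b = rng.standard_normal(n)
        res = phylo_paired_ttest(a, b, tree, species=sp, df_convention="n-1")
        ref = stats.ttest_rel(a, b)
        assert res.tstat == pytest.approx(ref.statistic, abs=1e-8)
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-8)

    def test_constant_shift_sign(self, rng):
        n = 10
        tree = star_tree(n)
        a = rng.standard_normal(n)
        for c in (0.5, -0.5):
            res = phylo_paired_ttest(a + c, a + 2e-3 * rng.standard_normal(n),
                                     tree, species=tree.tip_labels)
            assert np.sign(res.tstat) == np.sign(c)

    def test_degenerate_zero_variance(self):
        tree = star_tree(5)
        res = phylo_paired_ttest(np.ones(5), np.ones(5), tree)
        assert res.degenerate

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            phylo_paired_ttest([1, 2], [2, 1], star_tree(2))


class TestDiet:
    @pytest.mark.parametrize(
        "level,code",
        [("never", 0), ("occasional", 0), ("secondary", 1), ("primary", 1)],
    )
    def test_recode(self, level, code):
        assert recode_diet(level) == code

    def test_unknown_level(self):
        with pytest.raises(ValueError):
            recode_diet("daily")

    def test_effect_recovery(self):
        ests = []
        for seed in range(20):
            spec = WorldSpec(n_species=100, diet_effect=1.0, seed=seed)
            tree = simulate_tree(100, seed=seed)
            tt, _ = simulate_species_traits(tree, spec)
            traits = pd.DataFrame(
                {
                    "species": tt.species,
                    "cmr": tt.p_cancer,  # noiseless species-level risk
                    "body_mass": tt.body_mass,
                    "life_expectancy": tt.life_expectancy_true,
                    "n_necropsied": 100,
                    "diet_mammal": [recode_diet(v) for v in tt.diet_mammal],
                }
            )
            fit, _ = diet_model(traits, tree, "mammal")
            ests.append(fit.coef_named("diet_mammal"))
        assert abs(np.mean(ests) - 1.0) <= 0.4

    def test_constant_flag_rank_deficient(self):
        tree = simulate_tree(20, seed=3)
        sp = sorted(tree.tip_labels)
        r = np.random.default_rng(0)
        traits = pd.DataFrame(
            {
                "species": sp,
                "cmr": r.uniform(0.01, 0.3, 20),
                "body_mass": r.lognormal(2, 1, 20),
                "life_expectancy": r.uniform(4, 30, 20),
                "n_necropsied": 50,
                "diet_fish": 0,
            }
        )
        with pytest.raises(SingularDesignError):
            diet_model(traits, tree, "fish")


class TestOrderContrasts:
    def _traits(self, means, n_per=4):
        rows = []
        for i, (order, mu) in enumerate(means.items()):
            for j in range(n_per):
                # symmetric jitter: group means stay exactly mu
                eps = 0.001 * (1 if j % 2 else -1)
                rows.append({"species": f"sp{i}_{j}", "order": order, "cmr": mu + eps})
        return pd.DataFrame(rows)

    def test_equal_means_zero_contrast(self):
        res = order_contrasts(self._traits({"A": 0.05, "B": 0.05}), adjust="none")
        assert res.contrasts.estimate.iloc[0] == pytest.approx(0.0)

    def test_balanced_marginal_means_are_group_means(self):
        res = order_contrasts(self._traits({"A": 0.02, "B": 0.10}), adjust="none")
        m = dict(zip(res.means.order, res.means.mean_risk_pct))
        assert m["A"] == pytest.approx(2.0) and m["B"] == pytest.approx(10.0)

    def test_three_orders_three_contrasts(self):
        res = order_contrasts(self._traits({"A": 0.02, "B": 0.05, "C": 0.1}))
        assert len(res.contrasts) == 3

    def test_min_species_rule_drops_small_orders(self):
        df = self._traits({"A": 0.02, "B": 0.05})
        df = pd.concat([df, pd.DataFrame([{"species": "solo", "order": "C", "cmr": 0.2}])])
        res = order_contrasts(df, adjust="none")
        assert set(res.means.order) == {"A", "B"}

    def test_single_order_rejected(self):
        with pytest.raises(ValueError):
            order_contrasts(self._traits({"A": 0.05}))


class TestZeroInflated:
    def _world_traits(self, seed=0, n=60):
        spec = WorldSpec(n_species=n, seed=seed)
        tree = simulate_tree(n, seed=seed)
        tt, _ = simulate_species_traits(tree, spec)
        r = np.random.default_rng(seed)
        n_nec = r.integers(25, 200, n)
        cmr = r.binomial(n_nec, tt.p_cancer) / n_nec
        return pd.DataFrame(
            {
                "species": tt.species,
                "cmr": cmr,
                "n_necropsied": n_nec,
                "body_mass": tt.body_mass,
                "life_expectancy": tt.life_expectancy_true,
            }
        ), tree

    def test_zero_split_exhaustive_and_disjoint(self):
        traits, tree = self._world_traits(2)
        fit = fit_zero_inflated(traits, tree)
        z, nz = set(fit.zero_species), set(fit.nonzero_species)
        saturated = {s for s in traits.species if traits.set_index("species").cmr[s] >= 1}
        assert z.isdisjoint(nz)
        assert z | nz | saturated == set(traits.species)

    def test_all_nonzero_skips_detection(self):
        traits, tree = self._world_traits(5)
        traits["cmr"] = np.clip(traits["cmr"], 0.01, 0.9)
        fit = fit_zero_inflated(traits, tree)
        assert fit.detection is None
        assert any("skipped" in n for n in fit.notes)

    def test_too_few_nonzero_refused(self):
        traits, tree = self._world_traits(7)
        traits.loc[traits.index[:-5], "cmr"] = 0.0
        with pytest.raises(ValueError, match="non-zero"):
            fit_zero_inflated(traits, tree)

    def test_high_leverage_exclusion_config(self):
        traits, tree = self._world_traits(9)
        victims = traits[traits.cmr > 0].species.iloc[:2].tolist()
        fit = fit_zero_inflated(traits, tree, exclude_species=victims)
        assert not set(victims) & set(fit.nonzero_species)
        assert any("exclusions" in n for n in fit.notes)

    def test_interaction_term_optional(self):
        traits, tree = self._world_traits(11)
        fit = fit_zero_inflated(traits, tree, interaction=True)
        assert "log_body_mass:log_life_expectancy" in fit.magnitude.names
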