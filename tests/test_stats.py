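"""Comparative statistics: PGLS, phyANOVA, Holm, Spearman, group summaries."""

import numpy as np
import pytest
from scipy import stats as sps

import footlever as fl
from footlever.stats import RegressionCoefficients, apply_regression


class TestHolm:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.05], [0.05]),
        ],
    )
    def test_small_cases(self, p, expected):
        assert np.allclose(fl.holm_adjust(p), expected)

    def test_matches_bruteforce_definition(self, rng):
        def brute(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            for rank, i in enumerate(order):
                candidates = [(m - r) * p[order[r]] for r in range(rank + 1)]
                adj[i] = min(1.0, max(candidates))
            return adj

        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            assert np.allclose(fl.holm_adjust(p), brute(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 9)
        _, adj, *_ = multipletests(p, method="holm")
        assert np.allclose(fl.holm_adjust(p), adj)

    def test_properties(self, rng):
        p = rng.uniform(0, 1, 10)
        adj = fl.holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            fl.holm_adjust([0.5, 1.2])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        rho, p = fl.spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0) and p < 1e-20
        rho, _ = fl.spearman_correlation(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 6, 15).astype(float)  # heavy ties
            y = rng.integers(0, 6, 15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = fl.spearman_correlation(x, y)
            ref_rho, ref_p = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref_rho, abs=1e-12)
            assert p == pytest.approx(ref_p, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho, _ = fl.spearman_correlation(x, y)
        rho2, _ = fl.spearman_correlation(np.exp(x), y**3 + 5 * y)
        assert rho2 == pytest.approx(rho, abs=1e-12)

    def test_exact_mode_agrees_with_t_on_small_n(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        rho_t, _ = fl.spearman_correlation(x, y, method="t")
        rho_e, p_e = fl.spearman_correlation(x, y, method="exact")
        assert rho_e == rho_t
        assert 0.0 <= p_e <= 1.0
        # exact p for a perfectly monotone short vector: 2 of n! orderings
        _, p_perfect = fl.spearman_correlation(np.arange(5.0), np.arange(5.0), method="exact")
        assert p_perfect == pytest.approx(2 / 120)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            fl.spearman_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError):
            fl.spearman_correlation([1, 1, 1], [1, 2, 3])


class TestPGLS:
    def test_star_tree_equals_ols(self, rng):
        newick = "(" + ",".join(f"t{i}:1" for i in range(12)) + ");"
        tree = fl.tree_from_newick(newick)
        taxa = [f"t{i}" for i in range(12)]
        X = rng.normal(size=(12, 2))
        y = 1.0 + X @ [0.5, -2.0] + rng.normal(0, 0.3, 12)
        fit = fl.pgls_fit(y, X, tree, taxa=taxa)
        beta_ols, *_ = np.linalg.lstsq(np.column_stack([np.ones(12), X]), y, rcond=None)
        assert np.allclose(fit.coefficients, beta_ols, atol=1e-8)

    def test_lambda_zero_equals_ols_on_any_tree(self, small_tree, rng):
        taxa = [f"t{i + 1}" for i in range(8)]
        X = rng.normal(size=(8, 1))
        y = rng.normal(size=8)
        fit = fl.pgls_fit(y, X, small_tree, taxa=taxa, lam=0.0)
        beta_ols, *_ = np.linalg.lstsq(np.column_stack([np.ones(8), X]), y, rcond=None)
        assert np.allclose(fit.coefficients, beta_ols, atol=1e-8)

    def test_profile_maximum_beats_endpoints(self, rng):
        tree, tab = fl.generate_cohort(fl.SyntheticCohortSpec(n_taxa=30, seed=21))
        X = np.column_stack([tab.theta_est_deg, tab.ln_body_mass])
        y = tab.theta_obs_deg.to_numpy()
        taxa = list(tab.species)
        fit = fl.pgls_fit(y, X, tree, taxa=taxa)
        for lam in (0.0, 1.0):
            fixed = fl.pgls_fit(y, X, tree, taxa=taxa, lam=lam)
            assert fit.log_likelihood >= fixed.log_likelihood - 1e-6

    def test_noiseless_cohort_recovers_beta_exactly(self):
        spec = fl.SyntheticCohortSpec(n_taxa=25, residual_sd=0.0, seed=8)
        tree, tab = fl.generate_cohort(spec)
        X = np.column_stack([tab.theta_est_deg, tab.ln_body_mass])
        fit = fl.pgls_fit(tab.theta_obs_deg.to_numpy(), X, tree, taxa=list(tab.species))
        b = spec.beta_true
        assert np.allclose(fit.coefficients, [b.beta0, b.beta1, b.beta2], atol=1e-6)

    def test_rank_deficient_design_rejected(self, small_tree, rng):
        taxa = [f"t{i + 1}" for i in range(8)]
        x = rng.normal(size=8)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="singular|rank"):
            fl.pgls_fit(rng.normal(size=8), X, small_tree, taxa=taxa)

    def test_summary_table_shape(self, rng):
        tree, tab = fl.generate_cohort(fl.SyntheticCohortSpec(n_taxa=20, seed=3))
        X = np.column_stack([tab.theta_est_deg, tab.ln_body_mass])
        fit = fl.pgls_fit(
            tab.theta_obs_deg.to_numpy(), X, tree,
            taxa=list(tab.species), names=["theta_est", "ln_body_mass"],
        )
        s = fit.summary()
        assert list(s.index) == ["intercept", "theta_est", "ln_body_mass"]
        assert 0.0 <= fit.lambda_hat <= 1.0
        assert np.all((fit.p_values >= 0) & (fit.p_values <= 1))


class TestPhyANOVA:
    def test_overwhelming_group_shift_detected(self):
        tree = fl.generate_tree(20, seed=2)
        taxa, trait = fl.simulate_bm_traits(tree, sigma2=1.0, seed=5)
        groups = ["a"] * 10 + ["b"] * 10
        shifted = trait + np.where(np.array(groups) == "a", 10 * trait.std(), 0.0)
        res = fl.phy_anova(shifted, groups, tree, n_sim=200, seed=0, taxa=taxa)
        assert res.p_simulated <= 0.01

    def test_affine_invariance(self):
        tree = fl.generate_tree(16, seed=4)
        taxa, trait = fl.simulate_bm_traits(tree, sigma2=1.0, seed=9)
        groups = (["a", "b", "c", "d"] * 4)[:16]
        r1 = fl.phy_anova(trait, groups, tree, n_sim=150, seed=7, taxa=taxa)
        r2 = fl.phy_anova(5.0 + 3.0 * trait, groups, tree, n_sim=150, seed=7, taxa=taxa)
        assert r1.f_statistic == pytest.approx(r2.f_statistic, abs=1e-9)
        assert r1.p_simulated == r2.p_simulated

    def test_star_tree_matches_plain_anova_f(self, rng):
        newick = "(" + ",".join(f"t{i}:1" for i in range(15)) + ");"
        tree = fl.tree_from_newick(newick)
        taxa = [f"t{i}" for i in range(15)]
        trait = rng.normal(size=15)
        groups = (["a"] * 5) + (["b"] * 5) + (["c"] * 5)
        res = fl.phy_anova(trait, groups, tree, n_sim=100, seed=0, taxa=taxa)
        f_ref, _ = sps.f_oneway(trait[:5], trait[5:10], trait[10:])
        assert res.f_statistic == pytest.approx(f_ref)

    def test_small_group_filter_warns_and_drops(self):
        tree = fl.generate_tree(9, seed=6)
        taxa, trait = fl.simulate_bm_traits(tree, sigma2=1.0, seed=1)
        groups = ["a"] * 4 + ["b"] * 4 + ["solo"]
        with pytest.warns(UserWarning, match="solo"):
            res = fl.phy_anova(
                trait, groups, tree, n_sim=100, seed=0, taxa=taxa, min_group_size=2
            )
        assert res.groups == ("a", "b")
        assert set(res.pairwise_adjusted_p.index) == {"a", "b"}

    def test_pairwise_table_symmetric_in_unit_interval(self):
        tree = fl.generate_tree(12, seed=8)
        taxa, trait = fl.simulate_bm_traits(tree, sigma2=1.0, seed=2)
        groups = (["a", "b", "c"] * 4)[:12]
        res = fl.phy_anova(trait, groups, tree, n_sim=120, seed=3, taxa=taxa)
        P = res.pairwise_adjusted_p.to_numpy()
        assert np.allclose(P, P.T, equal_nan=True)
        off = ~np.eye(3, dtype=bool)
        assert np.all((P[off] >= 0) & (P[off] <= 1))


class TestRegressionHelpers:
    def test_identity_coefficients(self):
        coef = RegressionCoefficients(0, 1, 0)
        assert apply_regression(coef, 120, 7.0) == pytest.approx(120)

    @pytest.mark.parametrize(
        "coef, est, lnbm, expected",
        [
            (RegressionCoefficients(8.42, 0.43, 4.87), 125, 12.9, 125.0),
            (RegressionCoefficients(4.90, 0.48, 4.87), 95, 4.1, 70.5),
        ],
    )
    def test_published_coefficient_arithmetic(self, coef, est, lnbm, expected):
        assert apply_regression(coef, est, lnbm) == pytest.approx(expected, abs=0.05)

    def test_group_difference_summary_balanced(self):
        recs = fl.load_table3()
        pred = {r.species_id: r.theta_obs for r in recs}  # perfect predictions
        out = fl.group_difference_summary(recs, pred, mass_cutoff=10_000)
        assert np.allclose(out["mean_theta_obs_minus_theta_r_obs"], 0.0)
        assert out.loc["below", "n"] + out.loc["above", "n"] == len(recs)

    def test_group_difference_summary_empty_group_flagged(self):
        recs = fl.load_table3()
        pred = {r.species_id: r.theta_obs for r in recs}
        with pytest.warns(UserWarning, match="empty"):
            out = fl.group_difference_summary(recs, pred, mass_cutoff=0.001)
        assert out.loc["below", "n"] == 0
        assert np.isnan(out.loc["below", "mean_theta_obs_minus_theta_est"])
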