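import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from progbias.simulate import (
    SimulationConfig,
    SimulationError,
    draw_correlated_effect_sizes,
    draw_effect_sizes,
    run_gwas,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_study,
    draw_true_effects,
)

from conftest import SMALL_CONFIG


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="sum to 1"):
            SimulationConfig(frac_null=0.9, frac_inc_only=0.05,
                             frac_prog_only=0.01, frac_pleio=0.01)

    @pytest.mark.parametrize("kw", [dict(prevalence=0.0), dict(prevalence=1.0),
                                    dict(maf_range=(0.0, 0.4)),
                                    dict(maf_range=(0.01, 0.6)), dict(rho=1.5)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(SimulationError):
            SimulationConfig(**kw)

    def test_default_cluster_counts_match_design(self):
        counts = SimulationConfig().cluster_counts()
        assert counts == {"G0": 1900, "GI": 20, "GP": 20, "GIP": 60}


class TestEffectSizes:
    def test_zero_cluster_r2_gives_zero_effects(self):
        rng = np.random.default_rng(0)
        eff = draw_effect_sizes(50, 0.0, np.full(50, 0.25), rng)
        assert np.all(eff == 0)

    def test_negative_cluster_r2_rejected(self):
        with pytest.raises(SimulationError):
            draw_effect_sizes(5, -0.1, np.full(5, 0.25), np.random.default_rng(0))

    def test_variance_contributions_are_halfnormal_with_expected_mean(self):
        # back out r2 = effect^2 * 2 maf (1-maf); mean must be cluster_r2/n,
        # since the half-normal mean is scale*sqrt(2/pi)
        rng = np.random.default_rng(1)
        n, cluster_r2 = 200_000, 8.0
        mafs = np.full(n, 0.25)
        eff = draw_effect_sizes(n, cluster_r2, mafs, rng)
        r2 = eff ** 2 * 2 * 0.25 * 0.75
        assert np.mean(r2) == pytest.approx(cluster_r2 / n, rel=0.01)
        # formula spot check: r2 = 0.005 at maf 0.25 -> |effect| = 0.11547
        assert math.sqrt(0.005 / (2 * 0.25 * 0.75)) == pytest.approx(0.11547, abs=1e-5)
        # signs are symmetric
        assert abs(np.mean(np.sign(eff))) < 0.01

    def test_copula_preserves_rank_correlation_and_margins(self):
        rng = np.random.default_rng(2)
        n = 20_000
        mafs = np.full(n, 0.3)
        bx, by, realized = draw_correlated_effect_sizes(n, 5.0, 10.0, 0.7, mafs, rng)
        rank_corr = stats.spearmanr(bx, by).statistic
        assert rank_corr == pytest.approx(0.7, abs=0.03)
        # marginal variance contributions still average to cluster_r2/n
        assert np.mean(bx ** 2 * 2 * 0.3 * 0.7) == pytest.approx(5.0 / n, rel=0.05)
        assert np.mean(by ** 2 * 2 * 0.3 * 0.7) == pytest.approx(10.0 / n, rel=0.05)
        assert np.isfinite(realized)


class TestGenotypes:
    def test_hardy_weinberg_frequencies(self):
        rng = np.random.default_rng(3)
        g = simulate_genotypes(200_000, np.array([0.5]), rng)[:, 0]
        freqs = np.bincount(g.astype(int), minlength=3) / len(g)
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)

    def test_mean_genotype_tracks_maf(self):
        rng = np.random.default_rng(4)
        g = simulate_genotypes(100_000, np.array([0.01, 0.2]), rng)
        np.testing.assert_allclose(g.mean(axis=0), [0.02, 0.4], rtol=0.1)

    def test_deterministic_given_seed(self):
        mafs = np.array([0.1, 0.3])
        a = simulate_genotypes(100, mafs, np.random.default_rng(5))
        b = simulate_genotypes(100, mafs, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestPhenotypes:
    def test_exact_case_count_from_empirical_threshold(self):
        cfg = SimulationConfig(n_individuals=3001, n_snps=200, seed=0, prevalence=0.4)
        _, truth = simulate_study(cfg)
        assert truth.params["n_cases"] == math.ceil(0.4 * 3001)

    def test_liability_heritability_hits_target(self):
        cfg = SimulationConfig(**SMALL_CONFIG)
        master = np.random.SeedSequence(0)
        rngs = [np.random.default_rng(s) for s in master.spawn(3)]
        truth = draw_true_effects(cfg, rngs[0])
        g = simulate_genotypes(cfg.n_individuals, truth.df["maf"].to_numpy(), rngs[1])
        simulate_phenotypes(g, truth, cfg, rngs[2])
        assert truth.params["h2_liability_realized"] == pytest.approx(0.40, abs=1e-9)
        lo, hi = cfg.h2_prog_range
        assert lo <= truth.params["h2_progression"] <= hi
        lo, hi = cfg.confounder_var_range
        assert lo <= truth.params["confounder_fraction"] <= hi

    def test_infeasible_heritability_raises(self):
        # tiny incidence effect budget cannot reach 40% liability h2 with U~N(0,1)
        cfg = SimulationConfig(n_individuals=500, n_snps=100, seed=0,
                               r2_inc_only=0.01, r2_inc_pleio=0.01)
        with pytest.raises(SimulationError, match="h2_liability"):
            simulate_study(cfg)

    def test_null_model_progression_independent_of_incidence(self):
        # keep incidence genetics (the liability h2 target needs them) but
        # remove every incidence->progression pathway
        cfg = SimulationConfig(n_individuals=4000, n_snps=100, seed=1,
                               frac_null=0.94, frac_inc_only=0.02,
                               frac_prog_only=0.02, frac_pleio=0.02,
                               rho=0.0, lambda_=0.0, gamma=0.0)
        master = np.random.SeedSequence(cfg.seed)
        rngs = [np.random.default_rng(s) for s in master.spawn(3)]
        truth = draw_true_effects(cfg, rngs[0])
        g = simulate_genotypes(cfg.n_individuals, truth.df["maf"].to_numpy(), rngs[1])
        ph = simulate_phenotypes(g, truth, cfg, rngs[2])
        # progression retains its own genetics but shares nothing with the
        # liability beyond chance overlap
        non_genetic_prog = ph["progression"] - g @ truth.df["beta_gy_true"].to_numpy()
        r = np.corrcoef(ph["liability"], non_genetic_prog)[0, 1]
        assert abs(r) < 0.05


class TestRunGwas:
    def test_noiseless_linear_fit_is_exact(self):
        rng = np.random.default_rng(6)
        g = simulate_genotypes(200, np.array([0.3]), rng)
        res = run_gwas(g, 2.0 * g[:, 0], model="linear")
        assert res["beta"][0] == pytest.approx(2.0, abs=1e-10)
        assert res["p"][0] < 1e-100

    def test_linear_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        g = simulate_genotypes(500, np.full(5, 0.3), rng)
        y = g[:, 0] * 0.3 + rng.standard_normal(500)
        res = run_gwas(g, y, model="linear")
        for j in range(5):
            fit = sm.OLS(y, sm.add_constant(g[:, j])).fit()
            assert res["beta"][j] == pytest.approx(fit.params[1], abs=1e-10)
            assert res["se"][j] == pytest.approx(fit.bse[1], abs=1e-10)
            assert res["p"][j] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_logistic_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        g = simulate_genotypes(800, np.full(5, 0.3), rng)
        liab = g[:, 0] * 0.4 + rng.standard_normal(800)
        y = (liab > np.quantile(liab, 0.6)).astype(float)
        res = run_gwas(g, y, model="logistic")
        for j in range(5):
            fit = sm.Logit(y, sm.add_constant(g[:, j])).fit(disp=0)
            assert res["beta"][j] == pytest.approx(fit.params[1], abs=1e-8)
            assert res["se"][j] == pytest.approx(fit.bse[1], abs=1e-8)

    def test_monomorphic_snp_flagged_missing(self):
        g = np.ones((100, 2))
        g[:, 1] = np.repeat([0.0, 1.0, 2.0], [30, 40, 30])
        y = np.random.default_rng(9).standard_normal(100)
        res = run_gwas(g, y, model="linear")
        assert not res["converged"][0]
        assert np.isnan(res["beta"][0])
        assert res["converged"][1]

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(10)
        g = simulate_genotypes(1000, np.full(200, 0.3), rng)
        y = rng.standard_normal(1000)
        res = run_gwas(g, y, model="linear")
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_progression_sample_size_is_case_count(self, small_study):
        table, truth = small_study
        assert (table.df["n_prog"] == truth.params["n_cases"]).all()

    def test_logistic_requires_binary_phenotype(self):
        g = np.random.default_rng(11).binomial(2, 0.3, size=(50, 2)).astype(float)
        with pytest.raises(SimulationError, match="0/1"):
            run_gwas(g, np.linspace(0, 2, 50), model="logistic")


class TestSimulateStudy:
    def test_truth_respects_cluster_structure(self, small_study):
        table, truth = small_study
        df = truth.df
        g0 = df[df.cluster == "G0"]
        assert (g0["beta_gx_true"] == 0).all() and (g0["beta_gy_true"] == 0).all()
        assert (df[df.cluster == "GI"]["beta_gy_true"] == 0).all()
        assert (df[df.cluster == "GP"]["beta_gx_true"] == 0).all()
        gip = df[df.cluster == "GIP"]
        assert (gip["beta_gx_true"] != 0).all() and (gip["beta_gy_true"] != 0).all()

    def test_same_seed_reproduces_tables(self):
        cfg = SimulationConfig(n_individuals=1000, n_snps=100, seed=42)
        t1, tr1 = simulate_study(cfg)
        t2, tr2 = simulate_study(cfg)
        pd.testing.assert_frame_equal(t1.df, t2.df)
        pd.testing.assert_frame_equal(tr1.df, tr2.df)

    def test_degenerate_no_pleiotropy_config(self):
        cfg = SimulationConfig(n_individuals=2000, n_snps=200, seed=3,
                               frac_null=0.9, frac_inc_only=0.05,
                               frac_prog_only=0.05, frac_pleio=0.0,
                               r2_inc_only=1.0, r2_inc_pleio=0.0)
        table, truth = simulate_study(cfg)
        assert (truth.df["cluster"] != "GIP").all()

    def test_collider_bias_inflates_case_only_estimates_of_gi_variants(self, small_study):
        table, truth = small_study
        m = table.df.merge(truth.df, on="variant_id")
        z = (m["beta_prog"] / m["se_prog"]).abs()
        gi_z = z[m.cluster == "GI"].mean()
        g0_z = z[m.cluster == "G0"].mean()
        assert gi_z > g0_z + 0.2

    def test_full_population_progression_gwas_nearly_unbiased_for_gi(self):
        cfg = SimulationConfig(**{**SMALL_CONFIG, "n_individuals": 8000})
        master = np.random.SeedSequence(cfg.seed)
        rngs = [np.random.default_rng(s) for s in master.spawn(3)]
        truth = draw_true_effects(cfg, rngs[0])
        g = simulate_genotypes(cfg.n_individuals, truth.df["maf"].to_numpy(), rngs[1])
        ph = simulate_phenotypes(g, truth, cfg, rngs[2])
        full = run_gwas(g, ph["progression"], model="linear")
        cases = run_gwas(g, ph["progression"],
                         subset_mask=ph["incident"].astype(bool), model="linear")
        gi = (truth.df["cluster"] == "GI").to_numpy()
        # in the full population a GI variant's marginal effect is only
        # lambda*beta_GX (small); conditioning on cases adds the collider term
        full_err = np.abs(full["beta"][gi] - cfg.lambda_ * truth.df.loc[gi, "beta_gx_true"])
        case_err = np.abs(cases["beta"][gi])
        assert full_err.mean() < case_err.mean()

    def test_bias_slope_magnitude_orders_with_rho(self):
        # the cases-only bias of incidence-only variants is strongest when
        # the pleiotropic correlation is strongly positive (same direction
        # as the confounder effect)
        from oracles import empirical_bias_slope

        slopes = {}
        for rho in (-0.7, 0.7):
            acc = []
            for seed in (11, 12, 13):
                cfg = SimulationConfig(n_individuals=6000, n_snps=400,
                                       seed=seed, rho=rho)
                table, truth = simulate_study(cfg)
                acc.append(empirical_bias_slope(table, truth))
            slopes[rho] = np.mean(acc)
        assert abs(slopes[0.7]) > abs(slopes[-0.7])
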