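"""Synthetic cohort generator: genotypes, latent coarsening, outcome, export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from latentmr._glm import linear_scan, logistic_scan
from latentmr.simulate import (
    ConfigurationError,
    SimulationConfig,
    read_genotypes_vcf,
    simulate_cohort,
    simulate_genotypes,
    simulate_latent_and_categories,
    simulate_two_cohorts,
    export_summary_stats,
    write_genotypes_vcf,
)


class TestGenotypes:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_individuals=4, n_snps=2,
                               allele_freq_range=(0.5, 0.5))
        g1, f1 = simulate_genotypes(cfg, np.random.default_rng(9))
        g2, f2 = simulate_genotypes(cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(g1, g2)
        np.testing.assert_array_equal(f1, f2)

    def test_zero_frequency_gives_all_zero(self):
        cfg = SimulationConfig(n_individuals=50, n_snps=3,
                               allele_freq_range=(0.0, 0.0))
        g, _ = simulate_genotypes(cfg, np.random.default_rng(0))
        assert not g.any()

    def test_mean_allele_count_binomial(self):
        cfg = SimulationConfig(n_individuals=20000, n_snps=1,
                               allele_freq_range=(0.3, 0.3))
        g, _ = simulate_genotypes(cfg, np.random.default_rng(2))
        se = np.sqrt(2 * 0.3 * 0.7 / 20000)
        assert abs(g.mean() - 0.6) < 3 * se

    def test_entries_in_allele_count_range(self):
        cfg = SimulationConfig(n_individuals=500, n_snps=10)
        g, _ = simulate_genotypes(cfg, np.random.default_rng(3))
        assert set(np.unique(g)) <= {0, 1, 2}

    def test_invalid_frequency_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(allele_freq_range=(-0.1, 0.5))

    def test_ld_blocks_correlate_variants(self):
        cfg = SimulationConfig(n_individuals=4000, n_snps=6,
                               allele_freq_range=(0.4, 0.6),
                               ld_blocks=((0, 3, 0.9),))
        g, _ = simulate_genotypes(cfg, np.random.default_rng(4))
        r = np.corrcoef(g.T)
        assert r[0, 1] > 0.6 and abs(r[0, 4]) < 0.1


class TestLatentCoarsening:
    def test_null_genetics_reproduce_normal_frequencies(self):
        cfg = SimulationConfig(n_individuals=50000, n_snps=5, theta2_true=0.0,
                               mu_L=3.9, sigma_L_true=0.57,
                               confounder_effect=(0.0, 0.0), age_effect_L=0.0)
        g, _ = simulate_genotypes(cfg, np.random.default_rng(5))
        _, d = simulate_latent_and_categories(
            g, cfg, np.random.default_rng(6), alpha=np.zeros(5))
        p0 = stats.norm.cdf((3 - 3.9) / 0.57)
        p01 = stats.norm.cdf((4 - 3.9) / 0.57)
        for k, p in enumerate([p0, p01 - p0, 1 - p01]):
            se = np.sqrt(p * (1 - p) / 50000)
            assert abs((d == k).mean() - p) < 3.5 * se

    def test_interior_latent_gives_middle_category(self):
        cfg = SimulationConfig(n_individuals=200, n_snps=1, theta2_true=0.0,
                               mu_L=3.5, sigma_L_true=1e-4,
                               confounder_effect=(0.0, 0.0), age_effect_L=0.0)
        g, _ = simulate_genotypes(cfg, np.random.default_rng(7))
        L, d = simulate_latent_and_categories(
            g, cfg, np.random.default_rng(8), alpha=np.zeros(1))
        assert (d == 1).all()

    def test_default_category_frequencies_match_target(self):
        co = simulate_cohort(SimulationConfig(n_individuals=100_000), seed=21)
        freqs = np.bincount(co.data["exposure_category"], minlength=3) / co.n
        np.testing.assert_allclose(freqs, [0.071, 0.521, 0.408], atol=0.01)
        assert freqs.sum() == 1.0  # exact conservation

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(sigma_L_true=0.0)

    def test_generated_theta2_exact(self):
        co = simulate_cohort(SimulationConfig(n_individuals=500), seed=1)
        assert co.theta2_generated == pytest.approx(0.0072, abs=1e-12)


class TestMediatorAndOutcome:
    def test_event_rate_near_target(self):
        co = simulate_cohort(SimulationConfig(n_individuals=100_000), seed=13)
        assert co.event_rate == pytest.approx(0.029, abs=0.004)

    def test_event_times_within_followup(self):
        co = simulate_cohort(SimulationConfig(n_individuals=2000), seed=3)
        t = co.data["event_time"]
        assert (t > 0).all() and (t <= 12.0).all()
        assert 0 < co.event_rate < 1

    def test_no_mediation_share_decouples_mediator(self):
        cfg = SimulationConfig(n_individuals=30000, mediator_share=0.0,
                               theta2_true=0.05)
        co = simulate_cohort(cfg, seed=5)
        r = np.corrcoef(co.data["mediator"], co.data["latent_exposure"])[0, 1]
        assert abs(r) < 3.5 / np.sqrt(30000 - 3)

    def test_null_effects_give_independent_event_times(self):
        # score-test P of the latent exposure in a logistic outcome model is
        # uniform across replicates under the global null
        pvals = []
        for s in range(60):
            cfg = SimulationConfig(
                n_individuals=1200, n_snps=5, n_mediator_snps=2,
                beta_L_true=0.0, mediator_share=0.0, pleiotropy_sd=0.0,
                confounder_effect=(0.0, 0.0),
            )
            co = simulate_cohort(cfg, seed=700 + s)
            r, p = stats.pointbiserialr(
                co.data["event_indicator"], co.data["latent_exposure"]
            )
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_negative_baseline_hazard_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(baseline_hazard=-1.0)


class TestExportSummaryStats:
    def test_overlapping_cohorts_rejected(self, strong_cohort):
        with pytest.raises(ValueError, match="non-overlapping"):
            export_summary_stats(strong_cohort, strong_cohort)

    def test_contract_columns(self, cohort_pair):
        exp_tab, out_tab = export_summary_stats(*cohort_pair)
        cols = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se",
                "pval", "n"]
        assert list(exp_tab.columns) == cols and list(out_tab.columns) == cols

    def test_null_snp_effect_near_zero(self):
        cfg = SimulationConfig(n_individuals=20000, n_snps=3,
                               n_mediator_snps=2,
                               alpha=np.array([0.0, 0.05, 0.05]))
        exp, out = simulate_two_cohorts(cfg, seed=31)
        exp_tab, _ = export_summary_stats(exp, out)
        assert abs(exp_tab.beta[0]) < 3.5 * exp_tab.se[0]

    def test_probit_scale_attenuation(self):
        # alpha_hat estimates the per-allele latent effect in residual-SD
        # units, so alpha / sigma_L up to covariate adjustment
        cfg = SimulationConfig(n_individuals=50000, n_snps=2, n_mediator_snps=2,
                               theta2_true=0.02)
        exp, out = simulate_two_cohorts(cfg, seed=37)
        exp_tab, _ = export_summary_stats(exp, out)
        alpha = exp.snps["true_alpha"].to_numpy()[:2]
        expected = alpha / cfg.sigma_L_true
        np.testing.assert_allclose(exp_tab.beta, expected,
                                   atol=3.5 * exp_tab.se.max())


class TestScans:
    def test_logistic_scan_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 3000
        g = rng.binomial(2, 0.3, n).astype(float)
        c = rng.standard_normal(n)
        y = (rng.random(n) < stats.norm.cdf(-1.5 + 0.3 * g + 0.2 * c)).astype(float)
        tab = logistic_scan(g[:, None], y, c[:, None])
        X = sm.add_constant(np.column_stack([g, c]))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert tab.beta[0] == pytest.approx(ref.params[1], abs=1e-6)
        assert tab.se[0] == pytest.approx(ref.bse[1], rel=1e-4)

    def test_linear_scan_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 500
        g = rng.binomial(2, 0.4, n).astype(float)
        c = rng.standard_normal(n)
        y = 0.5 * g - 0.3 * c + rng.standard_normal(n)
        tab = linear_scan(g[:, None], y, c[:, None])
        ref = sm.OLS(y, sm.add_constant(np.column_stack([g, c]))).fit()
        assert tab.beta[0] == pytest.approx(ref.params[1], abs=1e-10)
        assert tab.se[0] == pytest.approx(ref.bse[1], rel=1e-10)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_scan(np.ones((10, 1)), np.zeros(10))


class TestIO:
    def test_vcf_round_trip(self, tmp_path):
        co = simulate_cohort(
            SimulationConfig(n_individuals=20, n_snps=4, n_mediator_snps=2),
            seed=2,
        )
        path = tmp_path / "geno.vcf"
        write_genotypes_vcf(co, path)
        G, meta = read_genotypes_vcf(path)
        np.testing.assert_array_equal(G, co.genotypes)
        assert list(meta["snp"]) == list(co.snps["snp"])

    def test_cohort_table_round_trip(self, tmp_path):
        co = simulate_cohort(
            SimulationConfig(n_individuals=30, n_snps=2, n_mediator_snps=2),
            seed=2,
        )
        path = tmp_path / "cohort.csv"
        co.to_table(path)
        back = pd.read_csv(path)
        assert back.shape[0] == 30
        assert "exposure_category" in back.columns
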