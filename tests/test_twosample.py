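"""Summary-statistic MR estimators, harmonisation and standardisation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from latentmr.twosample import (
    Egger,
    IVW,
    RAPS,
    WeightedMedian,
    cochran_q,
    egger,
    harmonise,
    ivw,
    raps,
    standardise_and_rescale,
    weighted_median,
    weighted_median_point,
)

from conftest import make_instruments


def summary_table(snps):
    """Exposure/outcome-style table from (snp, ea, oa, eaf, beta, se) tuples."""
    return pd.DataFrame(
        [
            {"snp": s, "effect_allele": ea, "other_allele": oa, "eaf": f,
             "beta": b, "se": se, "pval": 1e-9, "n": 10000}
            for s, ea, oa, f, b, se in snps
        ]
    )


class TestHarmonise:
    def test_aligned_tables_pass_through(self):
        exp = summary_table([("rs1", "A", "C", 0.3, 0.02, 0.005)])
        out = summary_table([("rs1", "A", "C", 0.3, -0.05, 0.02)])
        tab = harmonise(exp, out)
        assert tab.b[0] == -0.05 and tab.alpha_hat[0] == 0.02
        assert tab.sigma2_Z[0] == pytest.approx(2 * 0.3 * 0.7)

    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp = summary_table([("rs1", "A", "C", 0.3, 0.02, 0.005)])
        out = summary_table([("rs1", "C", "A", 0.7, -0.05, 0.02)])
        tab = harmonise(exp, out)
        assert tab.b[0] == 0.05

    def test_strand_flip_resolved_by_complement(self):
        exp = summary_table([("rs1", "A", "C", 0.3, 0.02, 0.005)])
        out = summary_table([("rs1", "T", "G", 0.3, -0.05, 0.02)])
        tab = harmonise(exp, out)
        assert tab.b[0] == -0.05

    def test_intermediate_frequency_palindrome_dropped(self):
        exp = summary_table([("rs1", "A", "T", 0.5, 0.02, 0.005),
                             ("rs2", "A", "C", 0.3, 0.02, 0.005)])
        out = summary_table([("rs1", "A", "T", 0.5, -0.05, 0.02),
                             ("rs2", "A", "C", 0.3, -0.05, 0.02)])
        with pytest.warns(UserWarning, match="palindromic"):
            tab = harmonise(exp, out)
        assert list(tab.snp) == ["rs2"]
        assert tab.attrs["n_dropped"] == 1

    def test_unresolvable_mismatch_dropped(self):
        exp = summary_table([("rs1", "A", "C", 0.3, 0.02, 0.005)])
        out = summary_table([("rs1", "A", "G", 0.3, -0.05, 0.02)])
        with pytest.warns(UserWarning, match="mismatch"):
            tab = harmonise(exp, out)
        assert tab.empty


class TestIVW:
    def test_equal_wald_ratios_returned_exactly(self):
        alpha = np.array([0.01, 0.02, 0.05])
        tab = make_instruments(alpha, b=-0.6 * alpha, se_b=[0.1, 0.02, 0.3])
        est = ivw(tab, theta2=0.01, sigma_L=0.5)
        assert est.beta == pytest.approx(-0.6, abs=1e-12)

    def test_matches_weighted_least_squares_oracle(self):
        import statsmodels.api as sm

        alpha = np.array([0.011, 0.024, 0.041])
        b = np.array([-0.01, -0.02, -0.01])
        se_b = np.array([0.02, 0.05, 0.03])
        tab = make_instruments(alpha, b, se_b=se_b)
        est = ivw(tab, theta2=0.01, sigma_L=0.5)
        wls = sm.WLS(b, alpha[:, None], weights=1 / se_b**2).fit()
        assert est.beta == pytest.approx(wls.params[0], abs=1e-12)

    def test_zero_exposure_effect_excluded_with_warning(self):
        tab = make_instruments([0.0, 0.02, 0.03], [-0.01, -0.012, -0.018])
        with pytest.warns(UserWarning, match="zero"):
            est = ivw(tab, theta2=0.01, sigma_L=0.5)
        assert est.n_snps == 2

    def test_random_effects_never_narrow_se(self):
        rng = np.random.default_rng(0)
        alpha = rng.uniform(0.01, 0.05, 20)
        b = -0.5 * alpha + rng.normal(0, 0.08, 20)  # overdispersed
        tab = make_instruments(alpha, b, se_b=0.02)
        fixed = IVW(theta2=0.01, sigma_L=0.5, random_effects="never").fit(tab)
        auto = IVW(theta2=0.01, sigma_L=0.5).fit(tab)
        assert auto.se_ >= fixed.se_

    def test_snp_order_equivariance(self):
        rng = np.random.default_rng(1)
        alpha = rng.uniform(0.01, 0.05, 12)
        b = -0.4 * alpha + rng.normal(0, 0.01, 12)
        tab = make_instruments(alpha, b)
        shuffled = tab.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert ivw(tab, 0.01, 0.5).beta == pytest.approx(
            ivw(shuffled, 0.01, 0.5).beta, abs=1e-12
        )


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_middle(self):
        assert weighted_median_point(np.array([1.0, 5.0, 2.0]),
                                     np.ones(3)) == 2.0

    def test_matches_brute_force_interpolation(self):
        rng = np.random.default_rng(2)
        ratios = rng.normal(size=9)
        w = rng.uniform(0.5, 2.0, 9)
        # independent brute force: scan the cumulative weight step function
        order = np.argsort(ratios)
        r, wn = ratios[order], w[order] / w.sum()
        cum = np.cumsum(wn) - wn / 2
        expected = np.interp(0.5, cum, r)
        assert weighted_median_point(ratios, w) == pytest.approx(expected)

    def test_majority_valid_beats_ivw_under_pleiotropy(self):
        # 49% of weight on variants with a shared pleiotropic offset
        rng = np.random.default_rng(3)
        m = 40
        alpha = rng.uniform(0.02, 0.04, m)
        b = -0.5 * alpha + rng.normal(0, 0.002, m)
        bad = np.arange(m)[:19]
        b[bad] += 0.05
        tab = make_instruments(alpha, b, se_alpha=0.001, se_b=0.01)
        wm = weighted_median(tab, 0.01, 0.5, n_boot=200, seed=0)
        iv = ivw(tab, 0.01, 0.5)
        assert abs(wm.beta + 0.5) < abs(iv.beta + 0.5)
        assert wm.beta == pytest.approx(-0.5, abs=0.1)

    def test_bootstrap_seed_determinism(self):
        tab = make_instruments([0.01, 0.02, 0.03], [-0.006, -0.011, -0.014])
        a = weighted_median(tab, 0.01, 0.5, n_boot=100, seed=5)
        b = weighted_median(tab, 0.01, 0.5, n_boot=100, seed=5)
        assert a.se == b.se


class TestEgger:
    def test_directional_pleiotropy_recovered(self):
        rng = np.random.default_rng(4)
        m = 60
        alpha = rng.uniform(0.01, 0.05, m)
        delta = 0.02
        b = delta - 0.5 * alpha + rng.normal(0, 0.001, m)
        est = egger(make_instruments(alpha, b, se_b=0.01), 0.01, 0.5)
        assert est.intercept == pytest.approx(delta, abs=0.005)
        assert est.beta == pytest.approx(-0.5, abs=0.05)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(5)
        alpha = rng.uniform(0.01, 0.05, 10)
        b = -0.4 * alpha + rng.normal(0, 0.005, 10)
        tab = make_instruments(alpha, b)
        flipped = tab.copy()
        flipped.loc[0, ["alpha_hat", "b"]] *= -1
        flipped.loc[0, "eaf"] = 1 - flipped.loc[0, "eaf"]
        a = egger(tab, 0.01, 0.5)
        f = egger(flipped, 0.01, 0.5)
        assert a.beta == pytest.approx(f.beta, abs=1e-12)
        assert a.intercept == pytest.approx(f.intercept, abs=1e-12)

    def test_low_spread_warns(self):
        tab = make_instruments([0.02, 0.0201, 0.0199, 0.02],
                               [-0.01, -0.0101, -0.0099, -0.01])
        with pytest.warns(UserWarning, match="spread"):
            egger(tab, 0.01, 0.5)


class TestRAPS:
    def test_vanishing_exposure_error_recovers_ivw(self):
        rng = np.random.default_rng(6)
        alpha = rng.uniform(0.02, 0.05, 15)
        b = -0.5 * alpha + rng.normal(0, 1e-4, 15)
        tab = make_instruments(alpha, b, se_alpha=1e-9, se_b=0.02)
        r = raps(tab, 0.01, 0.5)
        i = ivw(tab, 0.01, 0.5)
        assert r.beta == pytest.approx(i.beta, abs=1e-4)

    def test_profile_grid_brackets_optimum(self):
        rng = np.random.default_rng(7)
        alpha = rng.uniform(0.01, 0.04, 20)
        b = -0.5 * alpha + rng.normal(0, 0.01, 20)
        tab = make_instruments(alpha, b, se_alpha=0.005, se_b=0.01)
        model = RAPS(theta2=0.01, sigma_L=0.5).fit(tab)
        a = tab["alpha_hat"].to_numpy()
        bb = tab["b"].to_numpy()
        se_a2 = tab["se_alpha"].to_numpy() ** 2
        se_b2 = tab["se_b"].to_numpy() ** 2
        tau2 = model.estimate_.tau2
        grid = np.linspace(model.beta_ - 0.5, model.beta_ + 0.5, 401)
        lls = [-RAPS._neg_profile(g, tau2, a, bb, se_a2, se_b2) for g in grid]
        assert abs(grid[int(np.argmax(lls))] - model.beta_) <= (
            grid[1] - grid[0]
        )

    def test_less_weak_instrument_bias_than_ivw(self):
        # F ~ 10 regime: IVW dilutes toward zero, RAPS does not
        rng = np.random.default_rng(8)
        reps, m = 500, 30
        alpha = np.full(m, 0.02)
        se_a, se_b = 0.0063, 0.02  # F ~ 10
        bias_i, bias_r = [], []
        for _ in range(reps):
            ah = alpha + se_a * rng.standard_normal(m)
            b = -0.5 * alpha + se_b * rng.standard_normal(m)
            tab = make_instruments(ah, b, se_alpha=se_a, se_b=se_b)
            bias_i.append(IVW(0.01, 0.5).fit(tab).beta_ + 0.5)
            bias_r.append(
                RAPS(0.01, 0.5, overdispersion=False).fit(tab).beta_ + 0.5
            )
        assert abs(np.mean(bias_r)) < abs(np.mean(bias_i))
        assert np.mean(bias_i) > 0.02  # dilution toward zero is visible


class TestStandardisation:
    def test_single_snp_arithmetic(self):
        tab = make_instruments([1.0], [-0.5], eaf=0.5)
        est = standardise_and_rescale(1.0, 0.1, tab, theta2=0.25, sigma_L=1.0)
        assert est.beta_G == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert est.beta_L == pytest.approx(np.sqrt(0.5) / 0.5, abs=1e-12)

    def test_zero_beta_stays_zero(self):
        tab = make_instruments([0.02], [0.0])
        est = standardise_and_rescale(0.0, 0.1, tab, 0.01, 0.5)
        assert est.beta_L == 0.0

    def test_empty_instruments_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            standardise_and_rescale(1.0, 0.1, make_instruments([], []), 0.01,
                                    0.5)

    def test_estimators_agree_on_clean_strong_data(self):
        rng = np.random.default_rng(9)
        m = 50
        alpha = rng.uniform(0.02, 0.06, m)
        b = -0.5 * alpha + rng.normal(0, 0.004, m)
        tab = make_instruments(alpha, b, se_alpha=1e-4, se_b=0.004)
        ests = [
            ivw(tab, 0.01, 0.5),
            weighted_median(tab, 0.01, 0.5, n_boot=200, seed=1),
            egger(tab, 0.01, 0.5),
            raps(tab, 0.01, 0.5),
        ]
        for a in ests:
            for bb in ests:
                joint = np.hypot(a.se_L, bb.se_L)
                assert abs(a.beta_L - bb.beta_L) < 2 * joint


class TestHeterogeneity:
    def test_cochran_q_chi2_under_null(self):
        rng = np.random.default_rng(10)
        reps, m = 400, 12
        qs = []
        alpha = np.full(m, 0.05)
        for _ in range(reps):
            b = -0.5 * alpha + 0.01 * rng.standard_normal(m)
            tab = make_instruments(alpha, b, se_alpha=1e-9, se_b=0.01)
            q, df = cochran_q(tab)
            qs.append(q)
        ks = stats.kstest(qs, "chi2", args=(m - 1,))
        assert ks.pvalue > 0.01
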