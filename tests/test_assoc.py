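"""Logistic fitting and the scan/stratified/LRT/conditional model suite."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import kstest, norm

from admixscan import ancestry, assoc, simulate
from admixscan.assoc import (
    bmi_category_3level,
    bmi_category_4level,
    categorical_interaction_lrt,
    conditional_scan,
    fit_logistic,
    interaction_scan,
    snp_interaction_tests,
    stratified_scan,
)


def two_by_two_design():
    """Cases: 30 exposed / 10 unexposed; controls: 20 exposed / 40 unexposed."""
    y = np.concatenate([np.ones(40), np.zeros(60)])
    x = np.concatenate([np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)])
    return np.column_stack([np.ones(100), x]), y


class TestFitLogistic:
    def test_matches_two_by_two_closed_form(self):
        X, y = two_by_two_design()
        fit = fit_logistic(X, y)
        assert fit.converged
        # OR = (30*40)/(10*20) = 6; Woolf SE = sqrt(1/30 + 1/10 + 1/20 + 1/40)
        assert fit.beta[1] == pytest.approx(np.log(6), abs=1e-6)
        assert fit.se()[1] == pytest.approx(np.sqrt(1 / 30 + 1 / 10 + 1 / 20 + 1 / 40), abs=1e-6)

    def test_matches_statsmodels_on_random_design(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(400), rng.normal(size=(400, 3))])
        eta = X @ np.array([-0.5, 0.8, -0.3, 0.1])
        y = (rng.random(400) < expit(eta)).astype(float)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(ours.beta, ref.params, atol=1e-6)
        assert np.allclose(ours.se(), ref.bse, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        fit = fit_logistic(np.column_stack([np.ones(40), x]), y)
        assert not fit.converged

    def test_one_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_aliased_column_dropped_and_recorded(self, rng):
        x = rng.normal(size=200)
        X = np.column_stack([np.ones(200), x, 2 * x])
        y = (rng.random(200) < expit(x)).astype(float)
        fit = fit_logistic(X, y)
        assert len(fit.dropped) == 1

    def test_wald_p_definition(self, small_cohort, admix_config):
        pcs = ancestry.compute_pcs(small_cohort.genotypes, k=10)
        res = interaction_scan(
            small_cohort.true_local_ancestry,
            small_cohort.covariates["bmi"].to_numpy(),
            small_cohort.covariates["age"].to_numpy(),
            pcs,
            small_cohort.phenotype,
        )
        ok = res[res["converged"]]
        expected = 2 * norm.sf(np.abs(ok["beta"] / ok["se"]))
        assert np.max(np.abs(ok["p"].to_numpy() - expected)) < 1e-12


class TestInteractionScan:
    def test_constant_la_untestable(self, rng):
        la = np.column_stack([np.ones(100), rng.integers(0, 3, 100)])
        res = interaction_scan(
            la, rng.normal(30, 5, 100), rng.normal(40, 10, 100),
            rng.normal(size=(100, 2)), rng.integers(0, 2, 100),
        )
        assert res.iloc[0]["reason"] == "untestable"
        assert res.iloc[1]["reason"] != "untestable"

    def test_affine_bmi_reencoding_scales_beta_exactly(self, small_cohort):
        la = small_cohort.true_local_ancestry
        bmi = small_cohort.covariates["bmi"].to_numpy()
        age = small_cohort.covariates["age"].to_numpy()
        pcs = ancestry.compute_pcs(small_cohort.genotypes, k=5)
        y = small_cohort.phenotype
        a = interaction_scan(la[:, :5], bmi, age, pcs, y)
        b = interaction_scan(la[:, :5], 3.0 * bmi - 12.0, age, pcs, y)
        ok = a["converged"] & b["converged"]
        assert np.allclose(a.loc[ok, "beta"], 3.0 * b.loc[ok, "beta"], rtol=1e-6)

    def test_null_interaction_p_uniform(self):
        # ~400 independent null tests; KS should not reject uniformity
        out = __import__("admixscan").evaluation.null_interaction_type1(
            n_tests=400, n_individuals=500, markers_per_cohort=100, seed=21
        )
        assert kstest(out["pvals"], "uniform").pvalue > 0.01



@pytest.fixture(scope="module")
def planted_stratum_cohort():
    panel = simulate.make_aim_panel(30, seed=31, n_chrom=3)
    acfg = simulate.AdmixtureConfig(seed=32)
    pcfg = simulate.PhenotypeConfig(n_individuals=4000, causal_marker=None, seed=33)
    cohort = simulate.simulate_cohort(panel, acfg, pcfg)
    rng = np.random.default_rng(34)
    bmi = cohort.covariates["bmi"].to_numpy()
    la = cohort.true_local_ancestry
    # LA effect ln(0.5) per copy in the obese stratum only
    eta = -0.3 + np.where(bmi >= 30, np.log(0.5), 0.0) * la[:, 7]
    y = (rng.random(len(bmi)) < expit(eta)).astype(int)
    return cohort, la, y


@pytest.fixture(scope="module")
def snp_data():
    rng = np.random.default_rng(51)
    n = 2500
    g = rng.binomial(2, 0.35, n).astype(float)
    bmi = np.clip(rng.normal(31, 8, n), 15, None)
    age = np.clip(rng.normal(41, 12, n), 18, None)
    pcs = rng.normal(size=(n, 4))
    eta = -1.0 + 0.05 * g + 0.01 * bmi + 0.035 * g * (bmi - 25)
    y = (rng.random(n) < expit(eta)).astype(float)
    return g, bmi, age, pcs, y


class TestStratifiedScan:
    def test_planted_obese_effect_recovered(self, planted_stratum_cohort):
        cohort, la, y = planted_stratum_cohort
        pcs = ancestry.compute_pcs(cohort.genotypes, k=4)
        res = stratified_scan(
            la[:, [7]], y, cohort.covariates["age"].to_numpy(), pcs,
            cohort.covariates["bmi"].to_numpy(),
        )
        res = res.set_index("stratum")
        assert res.loc[">30", "beta"] == pytest.approx(np.log(0.5), abs=0.25)
        assert abs(res.loc["<25", "beta"]) < 0.35
        assert abs(res.loc["25-30", "beta"]) < 0.35

    def test_sparse_stratum_missing_with_reason(self, rng):
        la = rng.integers(0, 3, size=(60, 2)).astype(float)
        bmi = np.full(60, 22.0)
        bmi[:10] = 35.0  # obese stratum: 10 people, few cases
        y = rng.integers(0, 2, 60)
        y[:10] = np.r_[np.ones(3), np.zeros(7)].astype(int)  # 3 cases < 10
        res = stratified_scan(la, y, rng.normal(40, 5, 60), rng.normal(size=(60, 2)), bmi)
        obese = res[res["stratum"] == ">30"]
        assert not obese["converged"].any()
        assert (obese["reason"] == "fewer than 10 cases").all()


class TestBmiCategories:
    def test_boundaries_left_closed(self):
        bmi = np.array([24.9, 25.0, 29.9, 30.0, 34.9, 35.0])
        assert list(bmi_category_3level(bmi)) == [0, 1, 1, 2, 2, 2]
        assert list(bmi_category_4level(bmi)) == [0, 1, 1, 2, 2, 3]


class TestCategoricalLrt:
    def _draw(self, n, inter_slope, seed):
        rng = np.random.default_rng(seed)
        grp = rng.integers(0, 2, n).astype(float)
        bmi = np.clip(rng.normal(30, 8, n), 15, None)
        age = np.clip(rng.normal(42, 12, n), 18, None)
        cat = bmi_category_4level(bmi)
        eta = -0.5 + 0.1 * cat - 0.4 * grp + inter_slope * grp * cat + 0.005 * age
        y = (rng.random(n) < expit(eta)).astype(float)
        return y, grp, bmi, age

    def test_statistic_nonnegative_and_df3(self):
        y, grp, bmi, age = self._draw(2000, 0.0, 1)
        res = categorical_interaction_lrt(y, grp, bmi, age)
        assert res.statistic >= 0
        assert res.df == 3

    def test_null_p_not_degenerate(self):
        ps = [
            categorical_interaction_lrt(*self._draw(800, 0.0, s)).p for s in range(40)
        ]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_power_for_planted_category_slope(self):
        y, grp, bmi, age = self._draw(5000, 0.4, 2)
        res = categorical_interaction_lrt(y, grp, bmi, age)
        assert res.p < 0.05
        # group ORs should increase across categories in the full model
        betas = res.stratum_or["beta"].to_numpy()
        assert betas[-1] > betas[0]


class TestSnpInteractionTests:
    def test_per_sd_beta_is_continuous_times_sd(self, snp_data):
        g, bmi, age, pcs, y = snp_data
        res = snp_interaction_tests(g, bmi, age, pcs, y).set_index("term")
        sd = bmi.std(ddof=1)
        assert res.loc["SNPxBMIsd", "beta"] == pytest.approx(
            res.loc["SNPxBMI", "beta"] * sd, abs=1e-8
        )

    def test_trend_and_continuous_agree_in_sign(self, snp_data):
        g, bmi, age, pcs, y = snp_data
        res = snp_interaction_tests(g, bmi, age, pcs, y).set_index("term")
        assert np.sign(res.loc["SNPxBMIcat", "beta"]) == np.sign(res.loc["SNPxBMI", "beta"])

    def test_low_maf_skipped(self, snp_data, rng):
        _, bmi, age, pcs, y = snp_data
        g = rng.binomial(2, 0.04, len(y)).astype(float)
        res = snp_interaction_tests(g, bmi, age, pcs, y)
        assert not res["converged"].any()
        assert res["reason"].str.contains("MAF").all()


class TestConditionalScan:
    def test_conditioning_on_constant_leaves_estimate(self, snp_like=None):
        rng = np.random.default_rng(61)
        n = 1200
        g = rng.binomial(2, 0.4, n).astype(float)
        bmi = np.clip(rng.normal(31, 8, n), 15, None)
        age = np.clip(rng.normal(41, 12, n), 18, None)
        pcs = rng.normal(size=(n, 3))
        y = (rng.random(n) < expit(-0.5 + 0.03 * g * (bmi - 25))).astype(float)
        plain = snp_interaction_tests(g, bmi, age, pcs, y).set_index("term")
        cond = conditional_scan(g, bmi, age, pcs, y, np.ones(n)).set_index("term")
        assert cond.loc["SNPxBMI", "beta"] == pytest.approx(plain.loc["SNPxBMI", "beta"], abs=1e-8)

    def test_collinear_conditioning_flags_snp(self):
        rng = np.random.default_rng(62)
        n = 800
        g = rng.binomial(2, 0.4, n).astype(float)
        bmi = np.clip(rng.normal(31, 8, n), 15, None)
        age = np.clip(rng.normal(41, 12, n), 18, None)
        pcs = rng.normal(size=(n, 2))
        y = rng.integers(0, 2, n).astype(float)
        res = conditional_scan(g, bmi, age, pcs, y, g.copy())
        strat = res[res["term"] == "SNP"]
        # SNP and conditioning dosage identical within strata -> aliased
        assert (~strat["converged"]).any()

    def test_ancestry_confounding_attenuated(self):
        # SNP correlated with local ancestry; outcome driven by ancestry only.
        rng = np.random.default_rng(63)
        n = 4000
        la = rng.binomial(2, 0.2, n).astype(float)
        # high-delta marker: allele tracks ancestry strongly
        p_alt = np.where(la == 2, 0.9, np.where(la == 1, 0.5, 0.1))
        g = rng.binomial(2, p_alt / 2 + 0.25).astype(float)
        bmi = np.clip(rng.normal(31, 8, n), 15, None)
        age = np.clip(rng.normal(41, 12, n), 18, None)
        pcs = rng.normal(size=(n, 2))
        y = (rng.random(n) < expit(-0.5 - 0.5 * la)).astype(float)
        plain = snp_interaction_tests(g, bmi, age, pcs, y)
        cond = conditional_scan(g, bmi, age, pcs, y, la)
        b_plain = plain[(plain["term"] == "SNP") & (plain["stratum"] == ">30")]["beta"].iloc[0]
        b_cond = cond[(cond["term"] == "SNP") & (cond["stratum"] == ">30")]["beta"].iloc[0]
        assert abs(b_cond) < abs(b_plain)

    def test_missing_conditioning_rejected(self, rng):
        with pytest.raises(ValueError):
            conditional_scan(
                rng.binomial(2, 0.4, 50).astype(float),
                rng.normal(30, 5, 50), rng.normal(40, 5, 50),
                rng.normal(size=(50, 2)), rng.integers(0, 2, 50), np.ones(10),
            )
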