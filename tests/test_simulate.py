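import numpy as np
import pandas as pd
import pytest

import hepiron
from hepiron.classify import apply_exclusions
from hepiron.simulate import (B, C, LN, N, Marginal, OutcomeModel, SNP,
                              SexConfig, GeneratorConfig, _latent_correlation,
                              generate_cohort, generate_cohort_and_genotypes,
                              generate_genotype_array, inject_missingness,
                              default_study_config, lognormal_sigma)


def _flat_config(n=50, coeffs=None, intercept=40.0, sigma=0.0, marginals=None):
    marg = marginals or {"age": N(56.0, 9.0), "hff": LN(5.0, 5.0, upper=100.0),
                         "alcohol": LN(10.0, 20.0, upper=150.0)}
    sx = SexConfig(n=n, marginals=marg,
                   outcome=OutcomeModel(coefficients=coeffs or {},
                                        intercept=intercept, residual_sd=sigma))
    return GeneratorConfig(male=sx, female=sx)


class TestDeterminismAndBasics:
    def test_same_config_and_seed_bitwise_identical(self):
        cfg = default_study_config()
        a = generate_cohort(cfg, seed=7).data
        b = generate_cohort(cfg, seed=7).data
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_different_seed_differs(self):
        cfg = default_study_config()
        a = generate_cohort(cfg, seed=7).data
        b = generate_cohort(cfg, seed=8).data
        assert not a["hic"].equals(b["hic"])

    def test_zero_noise_intercept_only_outcome(self):
        c = generate_cohort(_flat_config(intercept=40.0, sigma=0.0), seed=3)
        np.testing.assert_array_equal(c.data["hic"].to_numpy(), 40.0)

    def test_lobe_mean_identity(self, study_cohort):
        df = study_cohort.data
        np.testing.assert_allclose(
            df["hic"], (df["hic_right"] + df["hic_left"]) / 2, rtol=0, atol=1e-9)
        np.testing.assert_allclose(
            df["hff"], (df["hff_right"] + df["hff_left"]) / 2, rtol=0, atol=1e-9)


class TestMarginalCalibration:
    def test_lognormal_sigma_reproduces_iqr(self):
        med, iqr = 7.02, 10.08
        sigma = lognormal_sigma(med, iqr)
        z75 = 0.6744897501960817
        q3 = med * np.exp(z75 * sigma)
        q1 = med * np.exp(-z75 * sigma)
        assert q3 - q1 == pytest.approx(iqr, rel=1e-12)

    @pytest.mark.parametrize("var,male_mu,male_sd,female_mu,female_sd", [
        ("age", 56.0, 9.3, 56.1, 9.0),
        ("bmi", 28.2, 4.1, 27.1, 5.2),
        ("sbp", 125.5, 16.0, 113.0, 14.9),
        ("hba1c", 5.56, 0.83, 5.51, 0.49),
    ])
    def test_continuous_means_within_3se(self, study_strata, var,
                                         male_mu, male_sd, female_mu, female_sd):
        for sex, mu, sd in (("male", male_mu, male_sd),
                            ("female", female_mu, female_sd)):
            vals = study_strata[sex].data[var].astype(float)
            se = sd / np.sqrt(len(vals))
            assert abs(vals.mean() - mu) < 3 * se

    def test_skewed_medians_near_targets(self, study_strata):
        # medians of (median, IQR)-parameterized marginals
        tg_m = study_strata["male"].data["triglycerides"].median()
        tg_f = study_strata["female"].data["triglycerides"].median()
        assert tg_m == pytest.approx(123.0, rel=0.15)
        assert tg_f == pytest.approx(89.4, rel=0.15)

    def test_categorical_frequencies_near_targets(self, study_strata):
        diab = (study_strata["male"].data["diabetes_status"] == "diabetes").mean()
        assert diab == pytest.approx(0.16, abs=0.08)

    def test_hff_bounded_and_alcohol_truncated(self, study_cohort):
        assert study_cohort.data["hff"].between(0, 100).all()
        assert (study_cohort.data["alcohol"] <= 150.0).all()


class TestCopulaCorrelation:
    def test_rank_correlation_target_recovered_at_large_n(self):
        # outcome-free config: HIC is a copula variable with target rho 0.48
        sx = SexConfig(n=10_000,
                       marginals={"age": N(56.1, 9.0),
                                  "hic": N(39.2, 4.1, lower=20)},
                       correlations=(("age", "hic", 0.48),))
        cfg = GeneratorConfig(male=sx, female=sx)
        c = generate_cohort(cfg, seed=5)
        f = c.stratify_by_sex()[1]
        rho = hepiron.spearman_rho(f.data["age"], f.data["hic"]).statistic
        assert 0.45 <= rho <= 0.51

    def test_non_psd_target_beyond_repair_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            _latent_correlation(["a", "b", "c"],
                                [("a", "b", 0.9), ("a", "c", 0.9),
                                 ("b", "c", -0.9)])

    def test_mild_inconsistency_is_repaired(self):
        R = _latent_correlation(["a", "b", "c"],
                                [("a", "b", 0.7), ("a", "c", 0.7)])
        w = np.linalg.eigvalsh(R)
        assert w.min() >= 0 and np.allclose(np.diag(R), 1.0)


class TestOutcomeModelRecovery:
    def test_ols_recovers_configured_coefficients_within_1pct(self):
        coeffs = {"hff": 2.08, "alcohol": 0.05, "age": 0.22}
        cfg = _flat_config(n=5000, coeffs=coeffs, intercept=30.0, sigma=0.05)
        c = generate_cohort(cfg, seed=11)
        m, _ = c.stratify_by_sex()
        X = np.column_stack([np.log(m.data["hff"]), m.data["alcohol"],
                             m.data["age"], np.ones(m.n)])
        est, *_ = np.linalg.lstsq(X, m.data["hic"].to_numpy(float), rcond=None)
        for est_k, true_k in zip(est[:3], [2.08, 0.05, 0.22]):
            assert est_k == pytest.approx(true_k, rel=0.01)

    def test_calibrated_mode_hits_target_sd(self, study_strata):
        for sex, sd in (("male", 4.7), ("female", 4.1)):
            s = study_strata[sex].data["hic"].std()
            assert s == pytest.approx(sd, rel=0.15)


class TestGenotypes:
    def test_mean_dosage_matches_frequency(self):
        rng = np.random.default_rng(0)
        d = generate_genotype_array((SNP("rs1", "A", 0.5),), 10_000, rng)
        assert 0.97 <= d.mean() <= 1.03

    def test_single_row_hard_calls(self):
        rng = np.random.default_rng(0)
        d = generate_genotype_array((SNP("rs1", "A", 0.3),), 1, rng)
        assert d.shape == (1, 1) and d[0, 0] in (0.0, 1.0, 2.0)

    def test_independent_snps_uncorrelated(self):
        rng = np.random.default_rng(1)
        d = generate_genotype_array(
            (SNP("rs1", "A", 0.3), SNP("rs2", "G", 0.4)), 10_000, rng)
        r = np.corrcoef(d[:, 0], d[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_dosage_mode_bounded_noise(self):
        rng = np.random.default_rng(2)
        d = generate_genotype_array((SNP("rs1", "A", 0.5),), 2000, rng,
                                    mode="dosage")
        assert d.min() >= 0.0 and d.max() <= 2.0
        assert not np.all(d == np.round(d))

    def test_frequency_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="frequency"):
            SNP("rs1", "A", 1.0)

    def test_snp_effects_enter_outcome(self):
        panel = (SNP("rs1", "A", 0.5, effect_male=3.0, effect_female=3.0),)
        cfg = default_study_config(n_male=400, n_female=147, snp_panel=panel)
        cohort, geno = generate_cohort_and_genotypes(cfg, seed=4)
        m = cohort.stratify_by_sex()[0].data
        d = geno.dosages.loc[m["id"]].to_numpy()[:, 0]
        slope = np.polyfit(d, m["hic"].astype(float), 1)[0]
        assert slope == pytest.approx(3.0, abs=1.0)


class TestMissingness:
    def test_exact_count_flagged_and_excluded(self):
        cfg = default_study_config(n_male=233, n_female=167)
        cohort = generate_cohort(cfg, seed=2)
        assert cohort.n == 400
        flagged = inject_missingness(cohort, 47, seed=2)
        from hepiron.classify import required_columns
        n_miss = flagged.missing_any(required_columns(flagged)).sum()
        assert n_miss == 47
        kept, log = apply_exclusions(flagged)
        assert kept.n == 353 and len(log) == 47

    def test_zero_missing_is_identity(self, study_cohort):
        out = inject_missingness(study_cohort, 0, seed=1)
        pd.testing.assert_frame_equal(out.data, study_cohort.data)

    def test_negative_count_rejected(self, study_cohort):
        with pytest.raises(ValueError):
            inject_missingness(study_cohort, -1, seed=1)

    def test_count_above_cohort_size_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            inject_missingness(tiny_cohort, 7, seed=1)
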