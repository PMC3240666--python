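"""Synthetic cohort generator: determinism, calibration, recovery."""

import numpy as np
import pandas as pd
import pytest

from hccstrat.simulate import (
    CalibrationError,
    ConfigurationError,
    SignatureBlock,
    SimulationConfig,
    generate_clinical,
    generate_cohort,
    generate_genotypes,
    generate_survival,
)
from hccstrat.survival import fit_cox, univariate_screen


class TestConfigValidation:
    @pytest.mark.parametrize("field,value,msg", [
        ("n_patients", 0, "n_patients"),
        ("n_genes", -3, "n_genes"),
        ("censoring_target", 1.0, "censoring_target"),
        ("censoring_target", 0.0, "censoring_target"),
        ("outlier_rate", 1.5, "outlier_rate"),
        ("maf_min", 0.0, "MAF"),
    ])
    def test_invalid_fields_named(self, field, value, msg):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=msg):
            cfg.validate()

    def test_signature_block_too_large(self):
        cfg = SimulationConfig(
            n_genes=50,
            signature_spec=[SignatureBlock("tumor", "good", 100, 1.0, 0.3)])
        with pytest.raises(ConfigurationError, match="block size"):
            cfg.validate()

    def test_rho_bound(self):
        cfg = SimulationConfig(
            signature_spec=[SignatureBlock("tumor", "good", 10, 1.0, 1.0)])
        with pytest.raises(ConfigurationError, match="rho"):
            cfg.validate()


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        cfg = dict(n_patients=60, n_genes=80, n_snps=40, n_eqtl=4,
                   n_csnp=2, signature_spec=[])
        a = generate_cohort(SimulationConfig(seed=7, **cfg))
        b = generate_cohort(SimulationConfig(seed=7, **cfg))
        assert a.clinical.equals(b.clinical)
        assert a.survival.equals(b.survival)
        assert a.expr_tumor.equals(b.expr_tumor)
        assert a.genotypes.equals(b.genotypes)
        assert a.truth.to_json() == b.truth.to_json()

    def test_different_seed_different_truth(self):
        cfg = dict(n_patients=60, n_genes=80, n_snps=40, n_eqtl=4,
                   n_csnp=2, signature_spec=[])
        a = generate_cohort(SimulationConfig(seed=1, **cfg))
        b = generate_cohort(SimulationConfig(seed=2, **cfg))
        assert not a.survival.equals(b.survival)


class TestClinicalMarginals:
    def test_means_within_three_se(self):
        cfg = SimulationConfig(n_patients=5000)
        rng = np.random.default_rng(5)
        clin = generate_clinical(cfg, rng)
        n = len(clin)
        checks = [
            ("age", cfg.age_mean, cfg.age_sd),
            ("ALBU", cfg.albu_mean, cfg.albu_sd),
            ("venous_infiltration", cfg.venous_frac,
             np.sqrt(cfg.venous_frac * (1 - cfg.venous_frac))),
        ]
        for col, mean, sd in checks:
            se = sd / np.sqrt(n)
            assert abs(clin[col].mean() - mean) < 3 * se, col
        male = (clin["sex"] == "M").mean()
        se = np.sqrt(cfg.male_frac * (1 - cfg.male_frac) / n)
        assert abs(male - cfg.male_frac) < 3 * se


class TestSurvivalGeneration:
    def test_censoring_calibrated_to_cohort_value(self):
        """Realized censored fraction hits the 67.8% target at n=2000."""
        cfg = SimulationConfig(n_patients=2000, signature_spec=[],
                               n_genes=10, n_snps=10, n_eqtl=1, n_csnp=1)
        rng = np.random.default_rng(11)
        clin = generate_clinical(cfg, rng)
        _, frac = generate_survival(clin, cfg, rng)
        assert abs(frac - 0.678) < 0.04

    def test_planted_binary_effect_recovered(self):
        """Multivariate Cox recovers beta = ln 2 within 3 SE at n=2000."""
        cfg = SimulationConfig(
            n_patients=2000, signature_spec=[], n_genes=10, n_snps=10,
            n_eqtl=1, n_csnp=1,
            clinical_effects={"venous_infiltration": np.log(2)})
        rng = np.random.default_rng(13)
        clin = generate_clinical(cfg, rng)
        y, _ = generate_survival(clin, cfg, rng)
        m = fit_cox(clin[["venous_infiltration"]].astype(float), y)
        assert abs(m.coef_[0] - np.log(2)) < 3 * m.se_[0]

    def test_null_effects_uniform_screen(self):
        """With all clinical effects zero the per-covariate univariate
        screen p-values behave like U(0,1)."""
        cfg = SimulationConfig(n_patients=400, signature_spec=[],
                               n_genes=10, n_snps=10, n_eqtl=1, n_csnp=1,
                               clinical_effects={}, frailty_sd=0.0)
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(40):
            clin = generate_clinical(cfg, rng)
            y, _ = generate_survival(clin, cfg, rng)
            noise = rng.normal(size=(400, 25))
            pvals.append(univariate_screen(noise, y)["p"].to_numpy())
        frac = (np.concatenate(pvals) < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_unknown_effect_column_rejected(self):
        cfg = SimulationConfig(clinical_effects={"no_such": 1.0})
        rng = np.random.default_rng(0)
        clin = generate_clinical(SimulationConfig(), rng)
        with pytest.raises(ConfigurationError, match="no_such"):
            generate_survival(clin, cfg, rng)


class TestGenotypes:
    def test_mean_dosage_tracks_maf(self):
        cfg = SimulationConfig(n_patients=10000, n_snps=30, n_eqtl=2,
                               n_csnp=2, maf_min=0.5, maf_max=0.5,
                               signature_spec=[])
        rng = np.random.default_rng(3)
        geno, *_ = generate_genotypes(cfg, rng)
        assert abs(geno.to_numpy().mean() - 1.0) < 0.03

    def test_planted_eqtls_in_cis_window(self):
        cfg = SimulationConfig(n_patients=50, n_snps=100, n_eqtl=10,
                               n_csnp=2, signature_spec=[], n_genes=200)
        rng = np.random.default_rng(9)
        geno, snp_pos, gene_pos, pairs, _ = generate_genotypes(cfg, rng)
        for snp, gene, _ in pairs:
            assert snp_pos.loc[snp, "chrom"] == gene_pos.loc[gene, "chrom"]
            assert abs(snp_pos.loc[snp, "bp"] -
                       gene_pos.loc[gene, "tss"]) <= cfg.eqtl_cis_bp

    def test_dosages_in_range(self, small_cohort):
        d = small_cohort.genotypes.to_numpy()
        assert set(np.unique(d)) <= {0, 1, 2}


class TestCohortBundle:
    def test_signature_planted_in_declared_stratum_only(self, small_cohort):
        """Signature genes associate with outcome inside their stratum
        and not outside it."""
        truth = small_cohort.truth
        planted = truth.signature_genes["tumor/good"]["genes"]
        strat = pd.Series(truth.stratum_labels)
        good = strat.index[strat == "good"]
        poor = strat.index[strat == "poor"]
        expr = small_cohort.expr_tumor
        y = small_cohort.survival
        p_good = univariate_screen(expr.loc[planted, good].T,
                                   y.loc[good])["p"].median()
        p_poor = univariate_screen(expr.loc[planted, poor].T,
                                   y.loc[poor])["p"].median()
        assert p_good < 0.1 < p_poor

    def test_truth_ids_subset_of_generated(self, small_cohort):
        t = small_cohort.truth
        genes = set(small_cohort.expr_tumor.index)
        snps = set(small_cohort.genotypes.index)
        for rec in t.signature_genes.values():
            assert set(rec["genes"]) <= genes
        assert set(t.csnp_ids) <= snps
        assert set(s for s, *_ in t.eqtl_pairs) <= snps

    def test_outlier_rate_zero_clean_mean(self):
        cfg = SimulationConfig(n_patients=400, n_genes=60, n_snps=10,
                               n_eqtl=1, n_csnp=1, outlier_rate=0.0,
                               nuisance_age_effect=0.0,
                               nuisance_sex_effect=0.0, signature_spec=[],
                               bg_rho=0.0, seed=21)
        c = generate_cohort(cfg)
        means = c.expr_tumor.mean(axis=1)
        se = 1.0 / np.sqrt(400)
        assert (np.abs(means) < 4 * se).mean() > 0.98
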