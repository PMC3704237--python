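"""Generative-model contracts: determinism, moments, degenerate configs."""

import numpy as np
import pandas as pd
import pytest

import sirenorm as sn
from sirenorm.errors import ConfigurationError
from sirenorm.genotypes import MISSING


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"rho_s": 1.5},
            {"sigma_s0_sq": -1.0},
            {"missing_rate": 1.0},
            {"n_qtl": 2000, "n_snps": 100},
            {"gxe_mode": "weird"},
            {"n_qtl": 1, "gxe_mode": "additive"},
            {"residual_class_variances": (0.0,) * 10},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            sn.SimulationConfig(**kwargs)

    def test_excess_qtl_variance_rejected(self):
        config = sn.SimulationConfig(n_sires=50, n_snps=20, n_qtl=5, seed=0)
        object.__setattr__(config, "qtl_var_fraction", 1.2)
        genotypes = sn.simulate_genotypes(config)
        with pytest.raises(ConfigurationError):
            sn.simulate_sire_effects(config, genotypes)


class TestGenotypes:
    def test_no_missing_when_rate_zero(self):
        config = sn.SimulationConfig(n_sires=50, n_snps=100, n_qtl=0, missing_rate=0.0, seed=1)
        assert not (sn.simulate_genotypes(config).calls == MISSING).any()

    def test_mean_dosage_at_maf_half(self):
        config = sn.SimulationConfig(
            n_sires=10000, n_snps=20, n_qtl=0, maf_range=(0.5, 0.5), seed=2
        )
        means = sn.simulate_genotypes(config).calls.mean(axis=0)
        se = np.sqrt(0.5 / 10000)  # binomial(2, .5)/1 variance 0.5
        assert np.all(np.abs(means - 1.0) < 4 * se)

    def test_deterministic(self):
        config = sn.SimulationConfig(n_sires=30, n_snps=50, n_qtl=0, missing_rate=0.1, seed=3)
        a = sn.simulate_genotypes(config)
        b = sn.simulate_genotypes(config)
        np.testing.assert_array_equal(a.calls, b.calls)
        assert a.snps.equals(b.snps)

    def test_missing_rate_applied(self):
        config = sn.SimulationConfig(n_sires=200, n_snps=200, n_qtl=0, missing_rate=0.05, seed=4)
        frac = (sn.simulate_genotypes(config).calls == MISSING).mean()
        assert abs(frac - 0.05) < 0.005


class TestPedigree:
    def test_deterministic(self):
        config = sn.SimulationConfig(n_sires=40, n_snps=4, n_qtl=0, seed=5)
        assert sn.simulate_pedigree(config).equals(sn.simulate_pedigree(config))

    def test_all_parents_present_or_unknown(self):
        config = sn.SimulationConfig(n_sires=40, n_snps=4, n_qtl=0, seed=6)
        ped = sn.simulate_pedigree(config)
        ids = set(ped["id"])
        for parent in ped["sire"]:
            assert parent == "0" or parent in ids


class TestSireEffects:
    def test_polygenic_variance_recovery(self):
        config = sn.SimulationConfig(n_sires=5000, n_snps=10, n_qtl=0, seed=7)
        genotypes = sn.simulate_genotypes(config)
        truth = sn.simulate_sire_effects(config, genotypes)
        s = truth.sire_effects
        mc_se0 = config.sigma_s0_sq * np.sqrt(2 / 5000)
        assert abs(s["s0"].var() - config.sigma_s0_sq) < 3 * mc_se0
        mc_se1 = config.sigma_s1_sq * np.sqrt(2 / 5000)
        assert abs(s["s1"].var() - config.sigma_s1_sq) < 3 * mc_se1

    def test_intercept_slope_correlation_recovery(self):
        config = sn.SimulationConfig(n_sires=5000, n_snps=200, n_qtl=20, seed=8)
        genotypes = sn.simulate_genotypes(config)
        truth = sn.simulate_sire_effects(config, genotypes)
        s = truth.sire_effects
        r = np.corrcoef(s["s0"], s["s1"])[0, 1]
        assert abs(r - 0.79) < 0.02

    def test_degenerate_correlation_one(self):
        config = sn.SimulationConfig(
            n_sires=500, n_snps=10, n_qtl=0, rho_s=1.0,
            sigma_s0_sq=100.0, sigma_s1_sq=100.0, seed=9,
        )
        genotypes = sn.simulate_genotypes(config)
        s = sn.simulate_sire_effects(config, genotypes).sire_effects
        np.testing.assert_allclose(s["s0"], s["s1"], atol=1e-5)

    def test_qtl_truth_recorded_and_calibrated(self):
        config = sn.SimulationConfig(n_sires=2000, n_snps=100, n_qtl=10,
                                     qtl_var_fraction=0.4, seed=10)
        genotypes = sn.simulate_genotypes(config)
        truth = sn.simulate_sire_effects(config, genotypes)
        assert len(truth.qtl_effects) == 10
        # genetic values from recorded QTL effects explain the configured share
        x = genotypes.calls[:, truth.qtl_effects["snp_index"]].astype(float)
        x = x - x.mean(axis=0)
        g0 = x @ truth.qtl_effects["alpha0"].to_numpy()
        assert g0.var(ddof=1) == pytest.approx(0.4 * config.sigma_s0_sq, rel=1e-6)


class TestDaughterRecords:
    def test_all_zero_variances_constant(self):
        config = sn.SimulationConfig(
            n_sires=5, daughters_per_sire=4, n_snps=4, n_qtl=0,
            sigma_s0_sq=0.0, sigma_s1_sq=0.0, rho_s=0.0,
            sigma_d0_sq=0.0, sigma_d1_sq=0.0, rho_d=0.0,
            residual_class_variances=(1e-12,) * 10, b_fixed=0.0, seed=11,
        )
        _, _, _, records = sn.simulate_dataset(config)
        np.testing.assert_allclose(records["cy"], config.mu, atol=1e-4)

    def test_per_class_residual_variances(self):
        config = sn.SimulationConfig(
            n_sires=40, daughters_per_sire=100, n_htd=400, n_snps=4, n_qtl=0,
            sigma_s0_sq=0.0, sigma_s1_sq=0.0, rho_s=0.0,
            sigma_d0_sq=0.0, sigma_d1_sq=0.0, rho_d=0.0, b_fixed=0.0, seed=12,
        )
        _, _, _, records = sn.simulate_dataset(config)
        from scipy.stats import chi2

        for label, group in records.groupby("residual_class"):
            target = config.residual_class_variances[label - 1]
            n = len(group)
            ratio = group["cy"].var(ddof=1) * (n - 1) / target
            assert chi2.ppf(0.0005, n - 1) < ratio < chi2.ppf(0.9995, n - 1)

    def test_daughter_moment_recovery(self):
        config = sn.SimulationConfig(n_sires=100, daughters_per_sire=30, n_snps=4,
                                     n_qtl=0, seed=13)
        genotypes = sn.simulate_genotypes(config)
        truth = sn.simulate_sire_effects(config, genotypes)
        sn.simulate_daughter_records(config, truth)
        d = truth.daughter_effects
        n = len(d)
        for col, target in (("d0", config.sigma_d0_sq), ("d1", config.sigma_d1_sq)):
            mc_se = target * np.sqrt(2 / n)
            assert abs(d[col].var() - target) < 3 * mc_se

    def test_deterministic_records(self):
        config = sn.SimulationConfig(n_sires=20, daughters_per_sire=5, n_snps=10, n_qtl=2, seed=14)
        *_, r1 = sn.simulate_dataset(config)
        *_, r2 = sn.simulate_dataset(config)
        pd.testing.assert_frame_equal(r1, r2)

    def test_daughters_range_config(self):
        config = sn.SimulationConfig(n_sires=50, daughters_per_sire=(5, 15), n_snps=4,
                                     n_qtl=0, seed=15)
        *_, records = sn.simulate_dataset(config)
        counts = records.groupby("sire_id")["daughter_id"].nunique()
        assert counts.between(5, 15).all() and counts.nunique() > 1


class TestMultiplicativeMode:
    def test_log_scale_has_no_slope_terms(self):
        config = sn.SimulationConfig.multiplicative(n_sires=50, daughters_per_sire=5, n_snps=10,
                                                    n_qtl=0, seed=16)
        _, _, truth, records = sn.simulate_dataset(config)
        assert (truth.sire_effects["s1"] == 0).all()
        assert (truth.daughter_effects["d1"] == 0).all()
        assert (records["cy"] > 0).all()

    def test_pure_scaling_no_reranking(self):
        config = sn.SimulationConfig.multiplicative(
            n_sires=150, daughters_per_sire=200, n_htd=400, n_snps=4, n_qtl=0, seed=17
        )
        _, _, _, records = sn.simulate_dataset(config)
        log_y = np.log(records["cy"])
        lo, hi = records["env"].quantile([0.1, 0.9])
        bottom = log_y[records["env"] <= lo].groupby(records["sire_id"]).mean()
        top = log_y[records["env"] >= hi].groupby(records["sire_id"]).mean()
        shared = bottom.index.intersection(top.index)
        r = np.corrcoef(bottom[shared], top[shared])[0, 1]
        assert r > 0.8  # attenuated only by sampling noise, not by re-ranking

    def test_intercept_qtl_multiplicative(self):
        config = sn.SimulationConfig.multiplicative(
            n_sires=300, daughters_per_sire=5, n_snps=50, n_qtl=1,
            qtl_var_fraction=0.5, seed=18,
        )
        genotypes = sn.simulate_genotypes(config)
        truth = sn.simulate_sire_effects(config, genotypes)
        assert len(truth.qtl_effects) == 1
        assert (truth.qtl_effects["alpha1"] == 0).all()
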