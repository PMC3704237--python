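"""Split protocol, per-SNP mixed model, q-values and validation rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sirenorm as sn
from sirenorm.association import estimate_pi0
from sirenorm.errors import DegenerateDataError
from sirenorm.kinship import RelationshipMatrix
from _oracles import bh_adjust, dense_gls_snp


class TestSplit:
    def test_progeny_panel_split_sizes(self):
        plan = sn.split_sires([f"S{i}" for i in range(2297)], n_validation=500, seed=1)
        assert len(plan.discovery) == 1797
        assert len(plan.validation) == 500

    def test_disjoint_union_and_determinism(self):
        ids = [f"S{i}" for i in range(50)]
        a = sn.split_sires(ids, n_validation=10, seed=7)
        b = sn.split_sires(ids, n_validation=10, seed=7)
        assert a.discovery == b.discovery and a.validation == b.validation
        assert set(a.discovery) | set(a.validation) == set(ids)
        assert not set(a.discovery) & set(a.validation)

    def test_oversized_validation_rejected(self):
        with pytest.raises(ValueError):
            sn.split_sires(["a", "b"], n_validation=2, seed=0)


def random_relationship(n, seed):
    rng = np.random.default_rng(seed)
    b = rng.standard_normal((n, n + 4))
    a = b @ b.T / (n + 4)
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    return RelationshipMatrix([f"S{i}" for i in range(n)], a + 0.05 * np.eye(n))


class TestSnpMlm:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        n = 40
        rel = RelationshipMatrix([f"S{i}" for i in range(n)], np.eye(n))
        x = rng.integers(0, 3, n).astype(float)
        y = rng.standard_normal(n)  # pure noise: gamma profiles to ~0
        fit = sn.fit_snp_mlm(y, x, rel)
        # with A = I the likelihood is flat in the variance ratio (the
        # polygenic term is indistinguishable from residual), so the fit
        # must collapse to ordinary least squares in effect, SE and p
        import statsmodels.api as smapi

        ols = smapi.OLS(y, smapi.add_constant(x)).fit()
        assert fit.beta == pytest.approx(ols.params[1], abs=1e-5)
        assert fit.se == pytest.approx(ols.bse[1], rel=1e-3)
        from scipy.stats import norm

        p_ols = 2 * norm.sf(abs(ols.params[1] / ols.bse[1]))
        assert fit.p == pytest.approx(p_ols, rel=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_gls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        rel = random_relationship(n, seed + 100)
        x = rng.integers(0, 3, n).astype(float)
        while np.ptp(x) == 0:
            x = rng.integers(0, 3, n).astype(float)
        L = np.linalg.cholesky(rel.values)
        y = 0.5 + 0.3 * x + L @ rng.standard_normal(n) + 0.5 * rng.standard_normal(n)
        fit = sn.fit_snp_mlm(y, x, rel)
        oracle = dense_gls_snp(y, x, rel.values)
        assert fit.beta == pytest.approx(oracle["beta"], abs=1e-6)
        assert fit.loglik >= oracle["loglik"] - 1e-8

    def test_monomorphic_errors(self):
        rel = random_relationship(6, 1)
        with pytest.raises(DegenerateDataError):
            sn.fit_snp_mlm(np.arange(6.0), np.ones(6), rel)

    def test_allele_flip_negates_beta_keeps_p(self):
        rng = np.random.default_rng(2)
        n = 60
        rel = random_relationship(n, 3)
        x = rng.integers(0, 3, n).astype(float)
        y = 0.2 * x + rng.standard_normal(n)
        f1 = sn.fit_snp_mlm(y, x, rel)
        f2 = sn.fit_snp_mlm(y, 2.0 - x, rel)
        assert f1.beta == pytest.approx(-f2.beta, rel=1e-6)
        assert f1.p == pytest.approx(f2.p, rel=1e-6)

    def test_power_with_planted_effect(self):
        rng = np.random.default_rng(4)
        n = 500
        rel = RelationshipMatrix([f"S{i}" for i in range(n)], np.eye(n))
        x = rng.binomial(2, 0.3, n).astype(float)
        y = rng.standard_normal(n)
        y += 0.5 * y.std() * x
        fit = sn.fit_snp_mlm(y, x, rel)
        assert fit.p < 1e-10


class TestRunGwas:
    def test_duplicate_snps_identical_rows(self, small_dataset):
        genotypes, _ = sn.run_qc(small_dataset["genotypes"])
        dup = genotypes.subset_snps(np.array([0, 0, 1]))
        ids = [str(i) for i in genotypes.individuals]
        ped = small_dataset["pedigree"]
        a = sn.build_numerator_relationship(ped, ids)
        rng = np.random.default_rng(5)
        est = pd.DataFrame({"sire_id": ids, "gp": rng.standard_normal(len(ids))})
        table = sn.run_gwas(est, dup, a, component="gp", add_qvalues=False)
        assert table.loc[0, "beta"] == pytest.approx(table.loc[1, "beta"], rel=1e-9)
        assert table.loc[0, "p"] == pytest.approx(table.loc[1, "p"], rel=1e-9)

    def test_planted_qtl_recovered(self):
        config = sn.SimulationConfig(n_sires=400, daughters_per_sire=2, n_snps=120,
                                     n_qtl=2, qtl_var_fraction=0.6, seed=21)
        genotypes = sn.simulate_genotypes(config)
        pedigree = sn.simulate_pedigree(config)
        truth = sn.simulate_sire_effects(config, genotypes)
        ids = [str(i) for i in genotypes.individuals]
        a = sn.build_numerator_relationship(pedigree, ids)
        # treat the true intercept effect, lightly noised, as the GP estimate
        rng = np.random.default_rng(22)
        s0 = truth.sire_effects["s0"].to_numpy()
        est = pd.DataFrame({"sire_id": ids, "gp": s0 + rng.standard_normal(len(ids)) * 0.2 * s0.std()})
        table = sn.run_gwas(est, genotypes, a, component="gp")
        significant = set(table.loc[table["significant"], "snp_id"])
        assert set(truth.qtl_effects["snp_id"]) <= significant

    def test_permuted_phenotype_type_i_error(self, small_dataset):
        config = sn.SimulationConfig(n_sires=300, daughters_per_sire=2, n_snps=2000,
                                     n_qtl=0, seed=23)
        genotypes = sn.simulate_genotypes(config)
        pedigree = sn.simulate_pedigree(config)
        ids = [str(i) for i in genotypes.individuals]
        a = sn.build_numerator_relationship(pedigree, ids)
        rng = np.random.default_rng(24)
        est = pd.DataFrame({"sire_id": ids, "gp": rng.permutation(np.arange(300.0))})
        table = sn.run_gwas(est, genotypes, a, component="gp", add_qvalues=False)
        rate = (table["p"] < 0.05).mean()
        assert 0.03 < rate < 0.07  # binomial(2000, 0.05) 99.9% interval


def test_manhattan_points_sorted_and_transformed():
    from sirenorm.association import manhattan_points

    table = pd.DataFrame(
        {
            "snp_id": ["a", "b", "c", "d"],
            "chrom": ["2", "1", "1", "10"],
            "pos": [100, 500, 200, 50],
            "p": [0.01, 1e-8, 0.5, np.nan],
            "failed": [False, False, False, True],
            "significant": [False, True, False, False],
        }
    )
    points = manhattan_points(table)
    assert len(points) == 3  # failed SNP dropped
    assert points["chrom"].tolist() == ["1", "1", "2"]
    assert points["pos"].tolist() == [200, 500, 100]
    assert points["neg_log10_p"].iloc[1] == pytest.approx(8.0)


class TestQvalues:
    def test_single_p_of_one(self):
        np.testing.assert_array_equal(sn.qvalues([1.0], pi0=1.0), [1.0])

    def test_hand_bh_case(self):
        q = sn.qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(10))
    def test_bh_equivalence_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=rng.integers(5, 40)), 4)
        np.testing.assert_allclose(sn.qvalues(p, pi0=1.0), bh_adjust(p), atol=1e-12)

    def test_pi0_on_uniform(self):
        p = np.random.default_rng(30).uniform(size=10000)
        assert 0.9 <= estimate_pi0(p) <= 1.1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sn.qvalues([])

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_in_rank_and_dominates(self, seed):
        p = np.random.default_rng(seed).uniform(size=50)
        q = sn.qvalues(p, pi0=1.0)
        order = np.argsort(p, kind="stable")
        # monotone non-decreasing in p-value rank
        assert np.all(np.diff(q[order]) >= -1e-12)
        # before the step-down the ranked quantities are pi0*m*p/rank;
        # the step-down can only lower them, never below the p-value itself
        ranks = np.empty(50, dtype=int)
        ranks[order] = np.arange(1, 51)
        assert np.all(q <= p * 50 / ranks + 1e-12)
        assert np.all(q >= p - 1e-12)
        assert np.all((q >= 0) & (q <= 1))


class TestFdrAtThreshold:
    def _table(self, pvals):
        p = np.asarray(pvals, dtype=float)
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(p))],
                "p": p,
                "q": sn.qvalues(p, pi0=1.0),
                "failed": False,
            }
        )

    def test_single_significant(self):
        p = np.ones(1000)
        p[3] = 1e-9
        table = self._table(p)
        assert sn.estimate_fdr_at_threshold(table) == pytest.approx(table.loc[3, "q"])

    def test_boundary_equals_bh_at_weakest_significant(self):
        rng = np.random.default_rng(31)
        p = np.concatenate([rng.uniform(0, 0.0009, 20), rng.uniform(0.01, 1, 480)])
        table = self._table(p)
        weakest = table.loc[table["p"] < 0.001, "p"].idxmax()
        assert sn.estimate_fdr_at_threshold(table) == pytest.approx(
            bh_adjust(p)[weakest], abs=1e-12
        )

    def test_no_significant_errors(self):
        with pytest.raises(DegenerateDataError):
            sn.estimate_fdr_at_threshold(self._table(np.full(10, 0.5)))


class TestValidation:
    def _setup(self, seed=40, beta_true=0.0, n=120):
        rng = np.random.default_rng(seed)
        config = sn.SimulationConfig(n_sires=n, daughters_per_sire=2, n_snps=30,
                                     n_qtl=0, seed=seed)
        genotypes = sn.simulate_genotypes(config)
        pedigree = sn.simulate_pedigree(config)
        ids = [str(i) for i in genotypes.individuals]
        a = sn.build_numerator_relationship(pedigree, ids)
        y = rng.standard_normal(n) + beta_true * genotypes.calls[:, 0]
        est = pd.DataFrame({"sire_id": ids, "gp": y})
        return genotypes, a, est, ids

    def test_rule_application_same_and_opposite_sign(self):
        genotypes, a, est, ids = self._setup(seed=41, beta_true=1.0)
        plan = sn.split_sires(ids, n_validation=40, seed=41)
        disc = est[est["sire_id"].isin(plan.discovery)]
        valid = est[est["sire_id"].isin(plan.validation)]
        table = sn.run_gwas(disc, genotypes, a, component="gp")
        result = sn.validate_snps(table, valid, genotypes, a, component="gp")
        row = result[result["snp_id"] == "SNP000001"].iloc[0]
        assert row["validated"] and row["p_validation"] < 0.01
        # flipping the validation-set trait flips the sign -> not validated
        flipped = valid.assign(gp=-valid["gp"])
        result2 = sn.validate_snps(table, flipped, genotypes, a, component="gp")
        row2 = result2[result2["snp_id"] == "SNP000001"].iloc[0]
        assert row2["p_validation"] < 0.01 and not row2["validated"]

    def test_empty_discovery_returns_empty(self):
        genotypes, a, est, ids = self._setup(seed=42)
        plan = sn.split_sires(ids, n_validation=40, seed=42)
        disc = est[est["sire_id"].isin(plan.discovery)]
        valid = est[est["sire_id"].isin(plan.validation)]
        table = sn.run_gwas(disc, genotypes, a, component="gp")
        table["significant"] = False
        result = sn.validate_snps(table, valid, genotypes, a, component="gp")
        assert result.empty
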