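"""Interaction mixed model, within-individual permutation null, test
selection and reGene FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stimeqtl as sq
from stimeqtl.reqtl import RandomInterceptLMM, ReqtlDesign
from tests.helpers import unit_variance_cfg, plant_fixed_cis


def make_design(seed, beta_rest, beta_stim, n_ind=100, noise=0.2,
                n_cov=14):
    rng = np.random.default_rng(seed)
    g_ind = rng.binomial(2, 0.3, size=n_ind).astype(float)
    cov_ind = rng.normal(size=(n_ind, n_cov))
    u = rng.normal(0, 0.5, size=n_ind)
    rows = {"y": [], "g": [], "c": [], "cov": [], "ind": []}
    for c, beta in ((0.0, beta_rest), (1.0, beta_stim)):
        rows["y"].append(beta * g_ind + u + rng.normal(0, noise, n_ind))
        rows["g"].append(g_ind)
        rows["c"].append(np.full(n_ind, c))
        rows["cov"].append(cov_ind)
        rows["ind"].append(np.arange(n_ind))
    return ReqtlDesign(y=np.concatenate(rows["y"]),
                       dosage=np.concatenate(rows["g"]),
                       condition=np.concatenate(rows["c"]),
                       covariates=np.vstack(rows["cov"]),
                       individual=np.concatenate(rows["ind"]))


class TestRandomInterceptLMM:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        groups = np.repeat(np.arange(60), 2)
        n = len(groups)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        u = rng.normal(0, 0.7, 60)
        y = X @ [1.0, 0.5, -0.3, 0.2] + u[groups] + rng.normal(0, 1, n)
        beta, se, s2, tau2 = RandomInterceptLMM(groups).fit(X, y)
        ref = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        assert np.allclose(beta, ref.fe_params, atol=1e-4)
        assert s2 == pytest.approx(ref.scale, rel=1e-3)
        assert tau2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]),
                                     rel=1e-2)
        # our SEs are the exact GLS covariance at the REML components
        V = s2 * np.eye(n) + tau2 * (groups[:, None] == groups[None, :])
        gls = np.sqrt(np.diag(np.linalg.inv(X.T @ np.linalg.inv(V) @ X)))
        assert np.allclose(se, gls, rtol=1e-3)

    def test_no_random_variance_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        groups = np.repeat(np.arange(50), 2)
        X = np.column_stack([np.ones(100), rng.normal(size=(100, 2))])
        y = X @ [0.5, 1.0, -1.0] + rng.normal(0, 1, 100)
        beta, se, _, tau2 = RandomInterceptLMM(groups).fit(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert tau2 / (tau2 + 1) < 0.2
        assert np.allclose(beta, ols, atol=0.05)


class TestInteractionFit:
    def test_no_response_gives_null_interaction(self):
        b, se, z = sq.fit_interaction_lmm(make_design(2, 0.5, 0.5))
        assert abs(b) < 0.1

    def test_differential_effect_recovered(self):
        betas = [sq.fit_interaction_lmm(make_design(s, 0.2, 0.8))[0]
                 for s in range(20)]
        assert np.mean(betas) == pytest.approx(0.6, abs=0.15)

    def test_signflip_interaction_near_minus_one(self):
        betas = [sq.fit_interaction_lmm(make_design(s + 50, 0.5, -0.5))[0]
                 for s in range(20)]
        assert np.mean(betas) == pytest.approx(-1.0, abs=0.15)

    def test_mixed_singleton_individuals_accepted(self):
        d = make_design(3, 0.3, 0.6, n_ind=40)
        # drop one condition for the first five individuals
        keep = ~((d.individual < 5) & (d.condition == 1.0))
        d2 = ReqtlDesign(d.y[keep], d.dosage[keep], d.condition[keep],
                         d.covariates[keep], d.individual[keep])
        b, se, z = sq.fit_interaction_lmm(d2)
        assert np.isfinite(z)


class TestPermutation:
    def test_p_emp_formula_and_bounds(self):
        res = sq.permute_condition_within_individual(
            make_design(4, 0.0, 1.5, noise=0.1), n_perm=200, seed=0,
            early_stop_s=None)
        assert res["s"] == 0
        assert res["p_emp"] == pytest.approx(1 / 201)
        assert res["p_emp"] >= 1 / (res["n_perm"] + 1)

    def test_null_design_p_emp_large(self):
        res = sq.permute_condition_within_individual(
            make_design(5, 0.4, 0.4, noise=0.3), n_perm=100, seed=0,
            early_stop_s=None)
        assert res["p_emp"] > 0.05
        assert res["s"] <= res["n_perm"]

    def test_seed_determinism(self):
        d = make_design(6, 0.2, 0.6)
        r1 = sq.permute_condition_within_individual(d, n_perm=50, seed=7,
                                                    early_stop_s=None)
        r2 = sq.permute_condition_within_individual(d, n_perm=50, seed=7,
                                                    early_stop_s=None)
        assert r1["s"] == r2["s"]

    def test_null_p_emp_approximately_uniform(self):
        # permutation p-values under the null over many genes
        ps = []
        for seed in range(60):
            res = sq.permute_condition_within_individual(
                make_design(seed + 100, 0.3, 0.3, n_ind=40, noise=0.5,
                            n_cov=2),
                n_perm=60, seed=seed, early_stop_s=None)
            ps.append(res["p_emp"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_early_stop_cannot_change_significance(self):
        d = make_design(8, 0.3, 0.3, noise=0.5)
        res = sq.permute_condition_within_individual(d, n_perm=500, seed=1,
                                                     early_stop_s=20)
        assert res["p_emp"] > 0.03  # stopped only once clearly null


class TestSelection:
    def _egenes(self, rows):
        return pd.DataFrame(rows, columns=["gene", "top_snp", "p_local",
                                           "egene"])

    def test_identical_top_snps_one_test(self, small_bundle):
        panel = small_bundle["panel"]
        snp = panel.snps.index[0]
        er = self._egenes([{"gene": "g", "top_snp": snp, "p_local": 1e-4,
                            "egene": True}])
        es = self._egenes([{"gene": "g", "top_snp": snp, "p_local": 1e-5,
                            "egene": True}])
        tests = sq.select_reqtl_tests(er, es, panel)
        assert len(tests) == 1

    def test_low_ld_top_snps_two_tests(self, small_bundle):
        panel = small_bundle["panel"]
        # SNPs from different chromosomes: r2 ~ 0
        snp_a = panel.snps.index[0]
        snp_b = panel.snps[panel.snps["chrom"]
                           != panel.snps.loc[snp_a, "chrom"]].index[0]
        er = self._egenes([{"gene": "g", "top_snp": snp_a, "p_local": 1e-4,
                            "egene": True}])
        es = self._egenes([{"gene": "g", "top_snp": snp_b, "p_local": 1e-5,
                            "egene": True}])
        tests = sq.select_reqtl_tests(er, es, panel)
        assert len(tests) == 2

    def test_high_ld_keeps_more_significant(self):
        from tests.conftest import make_panel
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.3, size=500).astype(float)
        b = a.copy()
        b[:20] = rng.binomial(2, 0.3, size=20)  # near-copy: r2 >> 0.8
        panel = make_panel(np.column_stack([a, b]))
        assert panel.ld_r2("s0", "s1") >= 0.8
        er = self._egenes([{"gene": "g", "top_snp": "s0",
                            "p_local": 1e-4, "egene": True}])
        es = self._egenes([{"gene": "g", "top_snp": "s1",
                            "p_local": 1e-6, "egene": True}])
        tests = sq.select_reqtl_tests(er, es, panel)
        assert len(tests) == 1
        assert tests.iloc[0]["snp"] == "s1"

    def test_single_condition_egene_one_test(self, small_bundle):
        panel = small_bundle["panel"]
        er = self._egenes([{"gene": "g", "top_snp": panel.snps.index[0],
                            "p_local": 1e-4, "egene": True}])
        es = self._egenes([])
        tests = sq.select_reqtl_tests(er, es, panel)
        assert len(tests) == 1
        assert tests.iloc[0]["source"] == "resting"


class TestReqtlFdr:
    def test_all_null_p_no_regenes(self):
        res = pd.DataFrame({"gene": ["a", "b"], "p_emp": [1.0, 1.0]})
        out = sq.reqtl_fdr(res)
        assert not out["significant"].any()

    def test_bh_agrees_with_shared_oracle(self):
        ps = np.array([0.001, 0.01, 0.2, 0.9])
        res = pd.DataFrame({"gene": list("abcd"), "p_emp": ps})
        out = sq.reqtl_fdr(res, alpha=0.05)
        reject, q = sq.bh_fdr(ps, alpha=0.05)
        assert np.array_equal(out["significant"].to_numpy(), reject)
        assert np.allclose(out["q"], q)

    def test_planted_reqtls_recovered_with_power(self):
        # interaction ~ 1.0 at n=100 pairs, permutation p + BH across a
        # mixed set of true and null tests
        rows = []
        for seed in range(10):
            d = make_design(seed + 300, 0.0, 1.0, n_ind=100, noise=0.5)
            res = sq.permute_condition_within_individual(
                d, n_perm=200, seed=seed, early_stop_s=50)
            rows.append({"gene": f"true{seed}", "p_emp": res["p_emp"],
                         "truth": True})
        for seed in range(10):
            d = make_design(seed + 400, 0.5, 0.5, n_ind=100, noise=0.5)
            res = sq.permute_condition_within_individual(
                d, n_perm=200, seed=seed, early_stop_s=50)
            rows.append({"gene": f"null{seed}", "p_emp": res["p_emp"],
                         "truth": False})
        out = sq.reqtl_fdr(pd.DataFrame(rows), alpha=0.05)
        power = out.loc[out["truth"], "significant"].mean()
        assert power >= 0.8
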