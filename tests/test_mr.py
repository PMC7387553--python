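"""Harmonisation, LD pruning, the four MR estimators and the consensus
verdict."""


import numpy as np
import pandas as pd
import pytest

import stimeqtl as sq
from stimeqtl.mr import InstrumentSet
from tests.conftest import make_panel


def eqtl_frame(snps, betas, ses, ea="G", oa="A", ps=None):
    n = len(snps)
    return pd.DataFrame({
        "beta": betas, "se": ses,
        "p": ps if ps is not None else np.full(n, 1e-6),
        "effect_allele": [ea] * n if isinstance(ea, str) else ea,
        "other_allele": [oa] * n if isinstance(oa, str) else oa},
        index=pd.Index(snps, name="snp"))


def iv_table(beta_exp, beta_out, se_out, se_exp=None):
    n = len(beta_exp)
    return pd.DataFrame({
        "beta_exp": beta_exp,
        "se_exp": se_exp if se_exp is not None else np.full(n, 0.05),
        "p_exp": np.full(n, 1e-8),
        "beta_out": beta_out, "se_out": se_out,
        "p_out": np.full(n, 1e-4)},
        index=pd.Index([f"s{i}" for i in range(n)], name="snp"))


class TestHarmonise:
    def test_swapped_alleles_flip_beta(self):
        e = eqtl_frame(["s1"], [0.5], [0.1], ea="G", oa="A")
        g = eqtl_frame(["s1"], [0.2], [0.05], ea="A", oa="G")
        out = sq.harmonise(e, g)
        assert out.loc["s1", "beta_out"] == pytest.approx(-0.2)

    def test_palindromic_snp_removed(self):
        e = eqtl_frame(["s1", "s2"], [0.5, 0.4], [0.1, 0.1],
                       ea=["A", "G"], oa=["T", "A"])
        g = eqtl_frame(["s1", "s2"], [0.2, 0.1], [0.05, 0.05],
                       ea=["A", "G"], oa=["T", "A"])
        out = sq.harmonise(e, g)
        assert list(out.index) == ["s2"]
        assert out.attrs["drop_reason"]["s1"] == "palindromic"

    def test_allele_mismatch_removed(self):
        e = eqtl_frame(["s1"], [0.5], [0.1], ea="G", oa="A")
        g = eqtl_frame(["s1"], [0.2], [0.05], ea="C", oa="A")
        out = sq.harmonise(e, g)
        assert out.empty

    def test_idempotent(self):
        e = eqtl_frame(["s1", "s2"], [0.5, -0.4], [0.1, 0.1])
        g = eqtl_frame(["s1", "s2"], [0.2, 0.3], [0.05, 0.05],
                       ea=["A", "G"], oa=["G", "A"])
        once = sq.harmonise(e, g)
        g2 = pd.DataFrame({
            "beta": once["beta_out"], "se": once["se_out"],
            "p": once["p_out"], "effect_allele": once["effect_allele"],
            "other_allele": once["other_allele"]}, index=once.index)
        twice = sq.harmonise(e, g2)
        assert np.allclose(once["beta_out"], twice["beta_out"])

    def test_no_overlap_fails(self):
        e = eqtl_frame(["s1"], [0.5], [0.1])
        g = eqtl_frame(["s9"], [0.2], [0.05])
        with pytest.raises(ValueError):
            sq.harmonise(e, g)


class TestLdPrune:
    def _candidates(self, snps, ps):
        return pd.DataFrame({"p_exp": ps},
                            index=pd.Index(snps, name="snp"))

    def test_perfectly_correlated_pair_keeps_one(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.3, 200).astype(float)
        panel = make_panel(np.column_stack([a, a]))
        out = sq.ld_prune(self._candidates(["s0", "s1"], [1e-8, 1e-6]),
                          panel)
        assert list(out.index) == ["s0"]  # more significant SNP retained

    def test_independent_snps_all_kept(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=(500, 4)).astype(float)
        panel = make_panel(g)
        out = sq.ld_prune(self._candidates([f"s{i}" for i in range(4)],
                                           [1e-8, 1e-7, 1e-6, 1e-5]), panel)
        assert len(out) == 4

    def test_greedy_matches_exhaustive_oracle(self):
        # constructed 5-SNP LD structure; the greedy-by-p retention must
        # match a direct simulation of the rule
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.4, 300).astype(float)
        g = np.column_stack([
            base,
            np.where(rng.random(300) < 0.9, base,
                     rng.binomial(2, 0.4, 300)),      # high LD with s0
            rng.binomial(2, 0.4, 300),
            rng.binomial(2, 0.4, 300),
            np.where(rng.random(300) < 0.9, base,
                     rng.binomial(2, 0.4, 300))])     # high LD with s0
        panel = make_panel(g.astype(float))
        ps = [1e-9, 1e-8, 1e-7, 1e-6, 1e-5]
        out = sq.ld_prune(self._candidates([f"s{i}" for i in range(5)], ps),
                          panel)
        # oracle: walk SNPs by ascending p, keep if r2 < 0.1 to all kept
        kept = []
        for snp in ["s0", "s1", "s2", "s3", "s4"]:
            if all(panel.ld_r2(snp, k) < 0.1 for k in kept):
                kept.append(snp)
        assert list(out.index) == kept
        assert "s0" in kept and "s1" not in kept and "s4" not in kept


class TestEstimators:
    def test_consensus_fixed_point_all_methods(self):
        # every ratio estimate exactly 0.5 -> all four estimates 0.5
        t = iv_table([0.5, 0.4, 0.2], [0.25, 0.20, 0.10],
                     [0.05, 0.05, 0.05], se_exp=[1e-8, 1e-8, 1e-8])
        ivs = InstrumentSet("g", "d", t)
        methods = sq.mr_estimates(ivs, n_boot=200, seed=0)
        for _, row in methods.iterrows():
            assert row["estimate"] == pytest.approx(0.5, abs=0.02), row["method"]

    def test_ivw_hand_example(self):
        t = iv_table([0.5, 0.4, 0.2], [0.25, 0.20, 0.10],
                     [0.05, 0.05, 0.05])
        est, se, p = sq.ivw_estimate(t)
        assert est == pytest.approx(0.5, abs=1e-12)

    def test_ivw_equals_precision_weighted_ratio_mean(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.2, 0.8, 6)
        by = 0.3 * bx + rng.normal(0, 0.02, 6)
        so = rng.uniform(0.02, 0.08, 6)
        t = iv_table(bx, by, so)
        est, _, _ = sq.ivw_estimate(t)
        ratios = by / bx
        w = (bx / so) ** 2   # precision of each ratio estimate
        assert est == pytest.approx(float((w * ratios).sum() / w.sum()),
                                    abs=1e-10)

    def test_weighted_median_reduces_to_plain_median(self):
        vals = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
        w = np.ones(5)
        assert sq.weighted_median(vals, w) == pytest.approx(np.median(vals))

    def test_causal_effect_recovered_by_all_methods(self):
        theta = 0.3
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bx = rng.uniform(0.1, 1.2, 12)
            sx = np.full(12, 0.01)
            so = np.full(12, 0.02)
            by = theta * bx + rng.normal(0, 0.02, 12)
            m = sq.mr_estimates(
                InstrumentSet("g", "d", iv_table(bx, by, so, se_exp=sx)),
                n_boot=200, seed=1).set_index("method")
            ok = all(abs(m.loc[n, "estimate"] - theta) < 0.1
                     for n in ("ivw", "weighted_median", "weighted_mode"))
            # Egger is far noisier; require its CI to cover the truth
            eg = abs(m.loc["egger", "estimate"] - theta) \
                < 2.5 * m.loc["egger", "se"]
            hits += ok and eg
        assert hits / 20 >= 0.9

    def test_directional_pleiotropy_flagged_by_egger(self):
        # the Egger intercept test needs many instruments spanning a
        # wide exposure-effect range to have power (the intercept is an
        # extrapolation to beta_exp = 0)
        flagged = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed + 100)
            n_iv = 40
            bx = rng.uniform(0.05, 1.5, n_iv)
            pleio = np.where(np.arange(n_iv) < n_iv // 2, 0.2, 0.0)
            by = 0.2 * bx + pleio + rng.normal(0, 0.01, n_iv)
            methods = sq.mr_estimates(
                InstrumentSet("g", "d",
                              iv_table(bx, by, np.full(n_iv, 0.01))),
                n_boot=100, seed=seed)
            flagged += methods.attrs["egger_intercept_p"] <= 0.05
        assert flagged / n_rep >= 0.7

    def test_zero_exposure_iv_dropped(self):
        t = iv_table([0.5, 0.0, 0.2, 0.4], [0.25, 0.1, 0.10, 0.2],
                     [0.05] * 4)
        est, se, p = sq.weighted_median_estimate(t, n_boot=100, seed=0)
        assert np.isfinite(est)

    def test_too_few_instruments_rejected(self):
        t = iv_table([0.5, 0.4], [0.25, 0.2], [0.05, 0.05])
        with pytest.raises(ValueError):
            sq.mr_estimates(InstrumentSet("g", "d", t))

    def test_null_effect_type_one_error(self):
        # valid IVs, zero causal effect: each method's rejection rate at
        # alpha=0.05 stays near nominal (parametric summary simulation)
        n_rep = 150
        rejections = {m: 0 for m in ("ivw", "weighted_median",
                                     "weighted_mode", "egger")}
        for seed in range(n_rep):
            rng = np.random.default_rng(seed + 500)
            bx_true = rng.uniform(0.1, 1.0, 8)
            sx = np.full(8, 0.01)
            so = np.full(8, 0.05)
            bx = rng.normal(bx_true, sx)
            by = rng.normal(0.0, so)
            methods = sq.mr_estimates(
                InstrumentSet("g", "d", iv_table(bx, by, so, se_exp=sx)),
                n_boot=100, seed=seed)
            for _, row in methods.iterrows():
                rejections[row["method"]] += row["p"] <= 0.05
        for method, count in rejections.items():
            assert count / n_rep <= 0.10, method
        # mode (kernel bandwidth) and Egger (residual-SE floor at 1,
        # t reference with few d.f.) are deliberately conservative, so a
        # two-sided nominal band applies only to IVW and the median
        for method in ("ivw", "weighted_median"):
            assert rejections[method] / n_rep >= 0.02, method


class TestVerdict:
    def _methods(self, ps, intercept_p):
        frame = pd.DataFrame({
            "method": ["ivw", "weighted_median", "weighted_mode", "egger"],
            "estimate": 0.3, "se": 0.1, "p": ps})
        frame.attrs["egger_intercept"] = 0.0
        frame.attrs["egger_intercept_p"] = intercept_p
        return frame

    def test_consensus_significant(self):
        v = sq.mr_verdict(self._methods([0.01, 0.02, 0.03, 0.04], 0.5))
        assert v["verdict"] == "causal_suggestive"
        assert v["n_methods_significant"] == 4

    def test_two_of_four_not_significant(self):
        v = sq.mr_verdict(self._methods([0.01, 0.02, 0.5, 0.6], 0.5))
        assert v["verdict"] == "not_significant"

    def test_pleiotropy_excludes_regardless(self):
        v = sq.mr_verdict(self._methods([0.001] * 4, 0.01))
        assert v["verdict"] == "excluded_pleiotropy"
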