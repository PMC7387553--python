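"""Calibration and recovery experiments at the study's design conditions.

These are the package's own benchmark simulations: global-null false-call
rates for the three multiple-testing procedures, and planted-effect
recovery for cis betas, genotype x condition interactions, mediation
proportions and MR causal effects. Problem sizes default to desk scale
(hundreds of genes, ~120 individuals, seeded) so a full pass runs in
minutes on one CPU.

All betas are in s.d. of expression per alternative allele; simulations
that state an effect in those units keep the raw expression variance near
one so the unit is meaningful after rank-normalisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import cis as cis_mod
from . import mediation as med_mod
from . import mr as mr_mod
from . import reqtl as reqtl_mod
from .cis import bh_fdr, effective_tests, hierarchical_correction
from .mediation import MediationTrio
from .mr import InstrumentSet
from .reqtl import ReqtlDesign


def _null_panel_expr(rng, n, n_genes, snps_per_gene, maf=0.3):
    g = rng.binomial(2, maf, size=(n, n_genes * snps_per_gene)).astype(float)
    y = rng.standard_normal((n, n_genes))
    return g, y


def cis_null_false_egene_rate(n_seeds: int = 10, n_genes: int = 500,
                              snps_per_gene: int = 50, n: int = 120,
                              fdr: float = 0.05, base_seed: int = 0) -> float:
    """Proportion of genes falsely declared eGenes by eigenMT-BH under a
    global null (no planted effects), averaged over seeds."""
    false_rates = []
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        g, y = _null_panel_expr(rng, n, n_genes, snps_per_gene)
        gc = g - g.mean(axis=0)
        yc = y - y.mean(axis=0)
        sg = (gc ** 2).sum(axis=0)
        sy = (yc ** 2).sum(axis=0)
        min_p = np.empty(n_genes)
        m_eff = np.empty(n_genes, dtype=int)
        dof = n - 2
        for j in range(n_genes):
            cols = slice(j * snps_per_gene, (j + 1) * snps_per_gene)
            r = (yc[:, j] @ gc[:, cols]) / np.sqrt(sy[j] * sg[cols])
            t = r * np.sqrt(dof / np.clip(1 - r ** 2, 1e-12, None))
            min_p[j] = 2 * stats.t.sf(np.abs(t), df=dof).min()
            m_eff[j] = effective_tests(g[:, cols])
        rec = hierarchical_correction(
            pd.Series(min_p, index=range(n_genes)),
            pd.Series(m_eff, index=range(n_genes)), fdr=fdr)
        false_rates.append(rec["egene"].mean())
    return float(np.mean(false_rates))


def _null_reqtl_design(rng, n_ind, n_cov=14):
    g = rng.binomial(2, 0.3, size=n_ind).astype(float)
    cov = rng.normal(size=(n_ind, n_cov))
    u = rng.normal(0, 0.5, size=n_ind)
    y, c = [], []
    for cond in (0.0, 1.0):
        y.append(0.4 * g + u + rng.normal(0, 0.6, n_ind))
        c.append(np.full(n_ind, cond))
    return ReqtlDesign(y=np.concatenate(y), dosage=np.tile(g, 2),
                       condition=np.concatenate(c),
                       covariates=np.vstack([cov, cov]),
                       individual=np.tile(np.arange(n_ind), 2))


def reqtl_null_false_rate(n_seeds: int = 10, n_tests: int = 200,
                          n_ind: int = 60, n_perm: int = 100,
                          fdr: float = 0.05, base_seed: int = 0) -> float:
    """Proportion of interaction tests falsely called significant by
    permutation + BH under a global null (eQTL present, no response)."""
    rates = []
    for s in range(n_seeds):
        ps = []
        for t in range(n_tests):
            rng = np.random.default_rng(base_seed + s * 100_000 + t)
            design = _null_reqtl_design(rng, n_ind)
            res = reqtl_mod.permute_condition_within_individual(
                design, n_perm=n_perm, seed=base_seed + s * 100_000 + t,
                early_stop_s=20)
            ps.append(res["p_emp"])
        reject, _ = bh_fdr(np.asarray(ps), alpha=fdr)
        rates.append(reject.mean())
    return float(np.mean(rates))


def trans_null_false_gene_rate(n_seeds: int = 10, n_genes: int = 500,
                               n_snps: int = 800, n: int = 120,
                               fdr: float = 0.05,
                               base_seed: int = 0) -> float:
    """Proportion of genes with a false genome-wide-FDR trans hit under a
    global null cross-chromosome scan."""
    rates = []
    dof = n - 2
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        g = rng.binomial(2, 0.3, size=(n, n_snps)).astype(float)
        y = rng.standard_normal((n, n_genes))
        gc = g - g.mean(axis=0)
        yc = y - y.mean(axis=0)
        r = (yc.T @ gc) / np.sqrt(np.outer((yc ** 2).sum(axis=0),
                                           (gc ** 2).sum(axis=0)))
        t = r * np.sqrt(dof / np.clip(1 - r ** 2, 1e-12, None))
        p = 2 * stats.t.sf(np.abs(t), df=dof)
        reject, _ = bh_fdr(p.ravel(), alpha=fdr)
        rates.append((reject.reshape(p.shape).any(axis=1)).mean())
    return float(np.mean(rates))


def cis_beta_recovery_error(n_seeds: int = 5, n_effects: int = 10,
                            n: int = 120, beta: float = 0.8,
                            maf: float = 0.3, base_seed: int = 0) -> float:
    """Mean absolute error of covariate-adjusted cis effect estimates for
    planted betas (s.d./allele) at the design sample size."""
    errors = []
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        for _ in range(n_effects):
            g = rng.binomial(2, maf, size=n).astype(float)
            cov = rng.normal(size=(n, 14))
            y = beta * g + cov @ rng.normal(0, 0.05, 14) \
                + rng.normal(0, np.sqrt(max(1 - beta ** 2 * 2 * maf
                                            * (1 - maf), 0.3)), n)
            y_res = cis_mod.residualise(y[:, None], cov)
            g_res = cis_mod.residualise(g[:, None], cov)
            bhat, *_ = cis_mod.marginal_stats(y_res, g_res, n - 16)
            errors.append(abs(float(bhat[0, 0]) - beta))
    return float(np.mean(errors))


def reqtl_power(n_seeds: int = 20, n_ind: int = 100, n_perm: int = 200,
                fdr: float = 0.05, base_seed: int = 0) -> float:
    """Power to recover planted interactions (half ordinary response,
    half sign-flips) as significant reQTL tests at 5% FDR, with an equal
    number of null tests in the BH set."""
    rows = []
    for s in range(n_seeds):
        rng_seed = base_seed + s
        if s % 2 == 0:
            beta_rest, beta_stim = 0.0, 1.0     # induced eQTL
        else:
            beta_rest, beta_stim = 0.5, -0.5    # sign flip
        design = _planted_reqtl_design(rng_seed, beta_rest, beta_stim,
                                       n_ind)
        res = reqtl_mod.permute_condition_within_individual(
            design, n_perm=n_perm, seed=rng_seed, early_stop_s=50)
        rows.append({"p_emp": res["p_emp"], "truth": True})
        null = _planted_reqtl_design(rng_seed + 10_000, 0.5, 0.5, n_ind)
        res0 = reqtl_mod.permute_condition_within_individual(
            null, n_perm=n_perm, seed=rng_seed + 10_000, early_stop_s=50)
        rows.append({"p_emp": res0["p_emp"], "truth": False})
    frame = pd.DataFrame(rows)
    reject, _ = bh_fdr(frame["p_emp"].to_numpy(), alpha=fdr)
    return float(reject[frame["truth"].to_numpy()].mean())


def _planted_reqtl_design(seed, beta_rest, beta_stim, n_ind, noise=0.5):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, size=n_ind).astype(float)
    cov = rng.normal(size=(n_ind, 14))
    u = rng.normal(0, 0.5, size=n_ind)
    y, c = [], []
    for cond, beta in ((0.0, beta_rest), (1.0, beta_stim)):
        y.append(beta * g + u + rng.normal(0, noise, n_ind))
        c.append(np.full(n_ind, cond))
    return ReqtlDesign(y=np.concatenate(y), dosage=np.tile(g, 2),
                       condition=np.concatenate(c),
                       covariates=np.vstack([cov, cov]),
                       individual=np.tile(np.arange(n_ind), 2))


def mediation_proportion_recovery(n_seeds: int = 50, n: int = 126,
                                  a: float = 1.0, b: float = 0.5,
                                  c_prime: float = 0.5, noise: float = 0.3,
                                  base_seed: int = 0) -> float:
    """Fraction of seeds whose estimated proportion mediated falls in
    [0.3, 0.7] for a planted half-mediated chain (truth 0.5)."""
    inside = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        g = rng.binomial(2, 0.3, size=n).astype(float)
        m = a * g + rng.normal(0, noise, n)
        y = b * m + c_prime * g + rng.normal(0, noise, n)
        trio = MediationTrio("s", "m", "y", g, m, y, np.empty((n, 0)),
                             np.arange(n))
        est = med_mod.estimate_paths(trio)
        inside += 0.3 <= est["prop_mediated"] <= 0.7
    return inside / n_seeds


def mr_ivw_coverage(n_seeds: int = 50, theta: float = 0.3, n_ivs: int = 8,
                    n_eqtl: int = 126, n_gwas: int = 50_000,
                    case_fraction: float = 0.1, maf: float = 0.3,
                    beta_exp: float = 1.0, base_seed: int = 0) -> float:
    """Coverage of the IVW 95% CI for a planted causal effect.

    Exposure summaries are drawn at the eQTL study's sample size;
    outcome summaries emulate a binary disease GWAS of ``n_gwas``
    individuals with the given case fraction (log-odds scale, so the
    per-allele SE carries the phi(1-phi) factor).
    """
    covered = 0
    var_g = 2 * maf * (1 - maf)
    phi = case_fraction
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        bx_true = rng.choice([-1, 1], n_ivs) * \
            np.abs(rng.normal(beta_exp, 0.05, n_ivs))
        se_exp = 1.0 / np.sqrt(n_eqtl * var_g)
        bx = rng.normal(bx_true, se_exp)
        se_out = 1.0 / np.sqrt(n_gwas * var_g * phi * (1 - phi))
        by = rng.normal(theta * bx_true, se_out)
        t = pd.DataFrame({
            "beta_exp": bx, "se_exp": se_exp,
            "p_exp": 2 * stats.norm.sf(np.abs(bx / se_exp)),
            "beta_out": by, "se_out": se_out,
            "p_out": 2 * stats.norm.sf(np.abs(by / se_out))},
            index=[f"s{i}" for i in range(n_ivs)])
        est, se, _ = mr_mod.ivw_estimate(t)
        covered += est - 1.96 * se <= theta <= est + 1.96 * se
    return covered / n_seeds
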