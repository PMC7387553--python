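"""Two-sample Mendelian randomisation of eGene expression on disease.

Instruments are significant cis-eSNPs harmonised against the outcome GWAS
(palindromic A/T and C/G variants removed), LD-pruned at r^2 < 0.1
(greedy, by ascending exposure p), and a gene-disease pair is analysed
only with at least three instruments. Four estimators are computed:

* IVW — inverse-variance-weighted regression of outcome on exposure betas
  through the origin (algebraically the precision-weighted mean of the
  per-variant ratio estimates);
* weighted median of ratio estimates, SE by parametric bootstrap;
* weighted mode — mode of a Gaussian kernel density over ratio estimates
  with the modified-Silverman bandwidth, SE by parametric bootstrap;
* MR-Egger — weighted regression with an intercept after orienting all
  exposure betas positive; the intercept's p tests directional pleiotropy.

Verdict: pleiotropy exclusion when the Egger intercept p <= 0.05;
otherwise suggestive causality when at least three of the four methods
reach p <= 0.05; no multiple-testing correction is applied to verdicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("stimeqtl")

MIN_IVS = 3
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class InstrumentSet:
    """Harmonised, pruned instruments for one gene-disease pair."""

    gene: str
    disease: str
    table: pd.DataFrame  # index snp; beta_exp, se_exp, p_exp, beta_out, se_out

    @property
    def n_ivs(self) -> int:
        return len(self.table)


def harmonise(eqtl: pd.DataFrame, gwas: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effect alleles to the exposure's effect (alt) allele.

    ``eqtl`` needs columns beta, se, p, effect_allele, other_allele
    (indexed by SNP); ``gwas`` likewise. Swapped alleles flip the outcome
    beta; palindromic (A/T, C/G) SNPs and allele mismatches are removed
    with reason codes in the ``drop_reason`` attr.
    """
    shared = eqtl.index.intersection(gwas.index)
    if shared.empty:
        raise ValueError("no overlapping SNPs between exposure and outcome")
    e = eqtl.loc[shared]
    g = gwas.loc[shared].copy()
    ambiguous = e["effect_allele"].map(COMPLEMENT) == e["other_allele"]
    same = (g["effect_allele"] == e["effect_allele"]) & \
           (g["other_allele"] == e["other_allele"])
    swapped = (g["effect_allele"] == e["other_allele"]) & \
              (g["other_allele"] == e["effect_allele"])
    g.loc[swapped, "beta"] = -g.loc[swapped, "beta"]
    out = pd.DataFrame({
        "beta_exp": e["beta"], "se_exp": e["se"], "p_exp": e["p"],
        "beta_out": g["beta"], "se_out": g["se"], "p_out": g["p"],
        "effect_allele": e["effect_allele"], "other_allele": e["other_allele"],
    })
    reasons = pd.Series("kept", index=shared)
    reasons[~(same | swapped)] = "allele_mismatch"
    reasons[ambiguous] = "palindromic"
    keep = (same | swapped) & ~ambiguous
    out = out.loc[keep]
    out.attrs["drop_reason"] = reasons[~keep].to_dict()
    return out


def ld_prune(candidates: pd.DataFrame, panel, r2: float = 0.1) -> pd.DataFrame:
    """Greedy LD pruning: keep SNPs by ascending exposure p, dropping any
    candidate with r^2 >= threshold against an already-retained SNP."""
    order = candidates.sort_values("p_exp", kind="stable").index
    kept: list[str] = []
    for snp in order:
        if all(panel.ld_r2(snp, other) < r2 for other in kept):
            kept.append(snp)
    return candidates.loc[kept]


def build_instruments(gene: str, disease: str, eqtl: pd.DataFrame,
                      gwas: pd.DataFrame, panel, r2: float = 0.1,
                      min_ivs: int = MIN_IVS) -> InstrumentSet | None:
    """Harmonise then prune; returns None (logged) below ``min_ivs``."""
    table = ld_prune(harmonise(eqtl, gwas), panel, r2=r2)
    if len(table) < min_ivs:
        logger.info("%s/%s skipped: %d instruments (<%d)", gene, disease,
                    len(table), min_ivs)
        return None
    return InstrumentSet(gene=gene, disease=disease, table=table)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _ratio_estimates(t: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios and first-order SEs; zero-exposure IVs are
    dropped with a warning."""
    bx = t["beta_exp"].to_numpy(float)
    nz = bx != 0
    if not nz.all():
        logger.warning("%d instruments dropped: zero exposure beta",
                       int((~nz).sum()))
    ratios = t["beta_out"].to_numpy(float)[nz] / bx[nz]
    se = t["se_out"].to_numpy(float)[nz] / np.abs(bx[nz])
    return ratios, se


def ivw_estimate(t: pd.DataFrame) -> tuple[float, float, float]:
    """IVW: regression through the origin with 1/se_out^2 weights (the
    precision-weighted mean of ratio estimates).

    The SE carries a multiplicative random-effects correction — scaled by
    the residual dispersion when that exceeds 1 — the standard guard
    against heterogeneity among instruments; under-dispersion is not
    rewarded (floor at the fixed-effect SE).
    """
    bx = t["beta_exp"].to_numpy(float)
    by = t["beta_out"].to_numpy(float)
    w = 1.0 / t["se_out"].to_numpy(float) ** 2
    sxx = (w * bx ** 2).sum()
    est = float((w * bx * by).sum() / sxx)
    se = float(np.sqrt(1.0 / sxx))
    if len(bx) > 1:
        dispersion = float((w * (by - est * bx) ** 2).sum() / (len(bx) - 1))
        se *= max(1.0, np.sqrt(dispersion))
    p = 2 * stats.norm.sf(abs(est / se))
    return est, se, float(p)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, v))


def weighted_median_estimate(t: pd.DataFrame, n_boot: int = 1000,
                             seed: int = 0) -> tuple[float, float, float]:
    """Weighted median of ratio estimates; SE by parametric bootstrap of
    the per-variant summary statistics."""
    ratios, se_r = _ratio_estimates(t)
    w = 1.0 / se_r ** 2
    est = weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    bx = t["beta_exp"].to_numpy(float)
    by = t["beta_out"].to_numpy(float)
    sx = t["se_exp"].to_numpy(float)
    sy = t["se_out"].to_numpy(float)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        nz = bxs != 0
        r = bys[nz] / bxs[nz]
        ws = (np.abs(bxs[nz]) / sy[nz]) ** 2
        boots[i] = weighted_median(r, ws)
    se = float(boots.std(ddof=1))
    p = 2 * stats.norm.sf(abs(est / se))
    return est, se, float(p)


def _silverman_bandwidth(x: np.ndarray, phi: float = 1.0) -> float:
    s = x.std(ddof=1)
    mad = stats.median_abs_deviation(x, scale="normal")
    spread = min(s, mad) if mad > 0 else s
    return phi * 0.9 * spread * len(x) ** (-1 / 5)


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray,
                   phi: float = 1.0) -> float:
    h = _silverman_bandwidth(ratios, phi)
    if h <= 0:
        return float(ratios[np.argmax(weights)])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = (weights[:, None]
            * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)).sum(0)
    return float(grid[np.argmax(dens)])


def weighted_mode_estimate(t: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                           phi: float = 1.0) -> tuple[float, float, float]:
    """Mode of the weighted kernel density of ratio estimates
    (modified-Silverman bandwidth); SE by parametric bootstrap."""
    ratios, se_r = _ratio_estimates(t)
    w = 1.0 / se_r ** 2
    est = _weighted_mode(ratios, w, phi)
    rng = np.random.default_rng(seed)
    bx = t["beta_exp"].to_numpy(float)
    by = t["beta_out"].to_numpy(float)
    sx = t["se_exp"].to_numpy(float)
    sy = t["se_out"].to_numpy(float)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        nz = bxs != 0
        r = bys[nz] / bxs[nz]
        ws = (np.abs(bxs[nz]) / sy[nz]) ** 2
        boots[i] = _weighted_mode(r, ws, phi)
    se = float(boots.std(ddof=1))
    p = 2 * stats.norm.sf(abs(est / se))
    return est, se, float(p)


def egger_estimate(t: pd.DataFrame) -> dict:
    """MR-Egger weighted regression with intercept, exposure betas
    oriented positive; t-based inference with an over-dispersion floor."""
    bx = t["beta_exp"].to_numpy(float).copy()
    by = t["beta_out"].to_numpy(float).copy()
    sy = t["se_out"].to_numpy(float)
    flip = bx < 0
    bx[flip] = -bx[flip]
    by[flip] = -by[flip]
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(len(bx)), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    dof = len(bx) - 2
    if dof <= 0:
        raise ValueError("MR-Egger needs at least 3 instruments")
    sigma2 = max(float((w * resid ** 2).sum()) / dof, 1.0)
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    tval = coef / se
    p = 2 * stats.t.sf(np.abs(tval), df=dof)
    return {"estimate": float(coef[1]), "se": float(se[1]), "p": float(p[1]),
            "intercept": float(coef[0]), "intercept_se": float(se[0]),
            "intercept_p": float(p[0])}


def mr_estimates(ivs: InstrumentSet, n_boot: int = 1000, seed: int = 0
                 ) -> pd.DataFrame:
    """All four estimators for one instrument set (long per-method frame)."""
    if ivs.n_ivs < MIN_IVS:
        raise ValueError("need at least three instruments")
    t = ivs.table
    rows = []
    est, se, p = ivw_estimate(t)
    rows.append({"method": "ivw", "estimate": est, "se": se, "p": p})
    est, se, p = weighted_median_estimate(t, n_boot=n_boot, seed=seed)
    rows.append({"method": "weighted_median", "estimate": est, "se": se, "p": p})
    est, se, p = weighted_mode_estimate(t, n_boot=n_boot, seed=seed + 1)
    rows.append({"method": "weighted_mode", "estimate": est, "se": se, "p": p})
    egger = egger_estimate(t)
    rows.append({"method": "egger", "estimate": egger["estimate"],
                 "se": egger["se"], "p": egger["p"]})
    frame = pd.DataFrame(rows)
    frame.attrs["egger_intercept"] = egger["intercept"]
    frame.attrs["egger_intercept_p"] = egger["intercept_p"]
    frame.attrs["gene"] = ivs.gene
    frame.attrs["disease"] = ivs.disease
    frame.attrs["n_ivs"] = ivs.n_ivs
    return frame


def mr_verdict(methods: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Consensus decision from the four methods and the Egger intercept."""
    n_sig = int((methods["p"] <= alpha).sum())
    intercept_p = methods.attrs["egger_intercept_p"]
    pleiotropy = intercept_p <= alpha
    if pleiotropy:
        verdict = "excluded_pleiotropy"
    elif n_sig >= 3:
        verdict = "causal_suggestive"
    else:
        verdict = "not_significant"
    return {"verdict": verdict, "n_methods_significant": n_sig,
            "pleiotropy": bool(pleiotropy),
            "egger_intercept": methods.attrs["egger_intercept"],
            "egger_intercept_p": intercept_p}


def run_mr(gene: str, disease: str, eqtl: pd.DataFrame, gwas: pd.DataFrame,
           panel, r2: float = 0.1, min_ivs: int = MIN_IVS,
           n_boot: int = 1000, seed: int = 0) -> dict | None:
    """End-to-end MR for one gene-disease pair (None when underpowered)."""
    ivs = build_instruments(gene, disease, eqtl, gwas, panel, r2=r2,
                            min_ivs=min_ivs)
    if ivs is None:
        return None
    methods = mr_estimates(ivs, n_boot=n_boot, seed=seed)
    verdict = mr_verdict(methods)
    return {"gene": gene, "disease": disease, "n_ivs": ivs.n_ivs,
            "methods": methods, "instruments": ivs.table, **verdict}
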