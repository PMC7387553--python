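"""Mediation analysis of trans effects through cis eGenes.

For a trio (eSNP exposure x, cis-eGene mediator m, trans-eGene outcome y)
and fixed covariates Z:

* ``a`` — exposure on mediator, OLS ``m ~ x + Z`` (the cis-eQTL effect);
* ``b`` and ``c'`` — from one multiple regression ``y ~ x + m + Z``:
  the mediator coefficient and the direct-effect coefficient;
* indirect effect ``a*b``; total effect ``a*b + c'``, which by the linear
  identity equals the exposure coefficient of ``y ~ x + Z``;
* H0: ab = 0 tested by a nonparametric bootstrap over individuals
  (percentile CI; two-sided p from the bootstrap sign crossing), BH
  correction across trios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cis import bh_fdr

logger = logging.getLogger("stimeqtl")


@dataclass
class MediationTrio:
    """Aligned per-sample vectors for one exposure/mediator/outcome trio."""

    snp: str
    cis_gene: str
    trans_gene: str
    dosage: np.ndarray
    mediator: np.ndarray
    outcome: np.ndarray
    covariates: np.ndarray
    individual: np.ndarray


def _ols_coefs(y: np.ndarray, cols: list[np.ndarray],
               covariates: np.ndarray) -> np.ndarray:
    """Coefficients of the leading ``cols`` in y ~ cols + covariates."""
    X = np.column_stack([np.ones(len(y)), *cols, covariates])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            "collinear design (mediator collinear with covariates?)")
    return coef[1:1 + len(cols)]


def estimate_paths(trio: MediationTrio) -> dict:
    """Point estimates (a, b, c', indirect, total, proportion mediated)."""
    a = float(_ols_coefs(trio.mediator, [trio.dosage], trio.covariates)[0])
    b, c_prime = _ols_coefs(trio.outcome, [trio.mediator, trio.dosage],
                            trio.covariates)
    indirect = a * float(b)
    total = indirect + float(c_prime)
    if abs(total) > 0:
        prop_raw = indirect / total
        prop = float(np.clip(prop_raw, -1.0, 2.0))
    else:
        prop_raw, prop = np.nan, np.nan
    return {"a": a, "b": float(b), "c_prime": float(c_prime),
            "indirect": indirect, "total": total,
            "prop_mediated": prop, "prop_mediated_raw": prop_raw}


def bootstrap_mediation(trio: MediationTrio, n_boot: int = 10_000,
                        seed: int = 0, ci: float = 0.95) -> dict:
    """Bootstrap p-value and percentile CI for the indirect effect ab.

    Individuals (not samples) are resampled with replacement, respecting
    the design's sampling unit. Degenerate resamples with constant dosage
    are redrawn (warned about when they exceed 1% of draws). The two-sided
    p-value is twice the smaller tail of the bootstrap distribution around
    zero (with the +1 guard used for permutation p-values).
    """
    rng = np.random.default_rng(seed)
    inds = np.unique(trio.individual)
    rows_of = {ind: np.flatnonzero(trio.individual == ind) for ind in inds}
    ab = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            take = rng.choice(inds, size=len(inds), replace=True)
            rows = np.concatenate([rows_of[ind] for ind in take])
            if trio.dosage[rows].std() > 0 and trio.mediator[rows].std() > 0:
                break
            redraws += 1
        sub = MediationTrio(trio.snp, trio.cis_gene, trio.trans_gene,
                            trio.dosage[rows], trio.mediator[rows],
                            trio.outcome[rows], trio.covariates[rows],
                            trio.individual[rows])
        est = estimate_paths(sub)
        ab[i] = est["indirect"]
    if redraws > 0.01 * n_boot:
        logger.warning("%d degenerate bootstrap resamples redrawn", redraws)
    lo, hi = np.quantile(ab, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    n_le = int((ab <= 0).sum())
    n_ge = int((ab >= 0).sum())
    p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1))
    return {"p_boot": p, "ci_low": float(lo), "ci_high": float(hi),
            "n_boot": n_boot}


def mediate_trios(trios: list[MediationTrio], n_boot: int = 10_000,
                  seed: int = 0) -> pd.DataFrame:
    """Estimate and bootstrap-test every trio; BH across trios."""
    rows = []
    for i, trio in enumerate(trios):
        est = estimate_paths(trio)
        boot = bootstrap_mediation(trio, n_boot=n_boot, seed=seed + i)
        rows.append({"snp": trio.snp, "cis_gene": trio.cis_gene,
                     "trans_gene": trio.trans_gene, **est, **boot})
    results = pd.DataFrame(rows)
    return mediation_fdr(results)


def mediation_fdr(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH over bootstrap p-values; adds q and significance flags."""
    out = results.copy()
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    reject, q = bh_fdr(out["p_boot"].to_numpy(), alpha=alpha)
    out["q"] = q
    out["significant"] = reject
    return out


def build_trio(study, panel, snp: str, cis_gene: str, trans_gene: str,
               condition: str,
               expression: pd.DataFrame | None = None) -> MediationTrio:
    """Assemble an aligned trio from one condition of a study.

    ``expression`` overrides the analysis-scale matrix (e.g. the INT
    matrix used in eQTL mapping).
    """
    expr = study.expression[condition] if expression is None else expression
    sheet = study.condition_samples(condition)
    inds = sheet["individual"].to_numpy()
    return MediationTrio(
        snp=snp, cis_gene=cis_gene, trans_gene=trans_gene,
        dosage=panel.dosages.loc[inds, snp].to_numpy(float),
        mediator=expr[cis_gene].to_numpy(float),
        outcome=expr[trans_gene].to_numpy(float),
        covariates=sheet[study.covariate_columns].to_numpy(float),
        individual=inds)
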