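"""Per-condition cis-eQTL scan with hierarchical multiple-testing control.

The scan is ordinary least squares of (transformed) expression on allele
dosage with fixed covariates. Covariates are projected out of both sides
once per condition (Frisch-Waugh-Lovell), which reproduces the full-model
dosage coefficient, standard error and t exactly while allowing the whole
gene x cis-SNP grid to be computed with dense linear algebra.

Multiple testing follows a two-level scheme: nominal p-values are locally
adjusted by the gene's effective number of independent SNPs (eigenvalues of
the genotype correlation matrix, chunked), the per-gene minima are then
controlled at 5% FDR across genes by Benjamini-Hochberg, and the global
cutoff is translated back into a per-gene nominal threshold used to call
significant eSNPs and to drive the conditional analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypePanel, ExpressionStudy

logger = logging.getLogger("stimeqtl")

CIS_WINDOW_BP = 1_000_000


# ---------------------------------------------------------------------------
# regression machinery (shared with the trans scan and conditional stages)
# ---------------------------------------------------------------------------

def residualise(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Project out covariates (plus an intercept) from columns of y."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if covariates is None or covariates.size == 0:
        c = np.ones((n, 1))
    else:
        c = np.column_stack([np.ones(n), covariates])
    coef, *_ = np.linalg.lstsq(c, y, rcond=None)
    return y - c @ coef


def marginal_stats(y_res: np.ndarray, g_res: np.ndarray, dof: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS slope/SE/t/p of each y column on each g column.

    Inputs must already be residualised on the same covariate set;
    ``dof`` is the full-model residual degrees of freedom
    (n - covariates - 2, counting intercept and dosage).
    Returns arrays of shape (n_y, n_g).
    """
    syy = (y_res ** 2).sum(axis=0)
    sgg = (g_res ** 2).sum(axis=0)
    sgg_safe = np.where(sgg > 0, sgg, np.nan)
    sxy = y_res.T @ g_res
    beta = sxy / sgg_safe[None, :]
    rss = syy[:, None] - beta ** 2 * sgg_safe[None, :]
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / sgg_safe[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    p = np.where(np.isfinite(t), np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    return beta, se, t, p


@dataclass
class ScanContext:
    """Pre-residualised data for one condition, reused across stages."""

    condition: str
    expression: pd.DataFrame          # samples x genes (analysis scale)
    dosages: pd.DataFrame             # samples x SNPs, aligned rows
    covariates: np.ndarray            # raw covariate matrix (n x k)
    genes: pd.DataFrame
    snps: pd.DataFrame
    individuals: pd.Series
    y_res: np.ndarray = field(init=False, repr=False)
    g_res: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.y_res = residualise(self.expression.to_numpy(float),
                                 self.covariates)
        self.g_res = residualise(self.dosages.to_numpy(float),
                                 self.covariates)

    @property
    def n(self) -> int:
        return self.expression.shape[0]

    @property
    def dof(self) -> int:
        k = 0 if self.covariates is None else self.covariates.shape[1]
        return self.n - k - 2

    def cis_snp_indices(self, gene: str, window_bp: int = CIS_WINDOW_BP
                        ) -> np.ndarray:
        row = self.genes.loc[gene]
        mask = (self.snps["chrom"].to_numpy() == row["chrom"]) & \
               (np.abs(self.snps["pos"].to_numpy() - row["tss"]) <= window_bp)
        return np.flatnonzero(mask)


def make_scan_context(study: ExpressionStudy, panel: GenotypePanel,
                      condition: str,
                      covariates: pd.DataFrame | None = None) -> ScanContext:
    """Align expression rows to genotype rows for one condition."""
    expr = study.expression[condition]
    inds = study.individuals(condition)
    missing = set(inds) - set(panel.individuals)
    if missing:
        raise KeyError(f"individuals missing genotypes: {sorted(missing)[:3]}")
    dosages = panel.dosages.loc[inds.to_numpy()]
    dosages.index = expr.index
    cov = study.covariates(condition) if covariates is None else covariates
    return ScanContext(condition=condition, expression=expr, dosages=dosages,
                       covariates=cov.to_numpy(float), genes=study.genes,
                       snps=panel.snps, individuals=inds)


def cis_scan(ctx: ScanContext, window_bp: int = CIS_WINDOW_BP,
             genes: list[str] | None = None) -> pd.DataFrame:
    """Association statistics for every gene x cis-SNP pair.

    Returns a long DataFrame with columns gene, snp, beta, se, t, p, n.
    Genes without cis SNPs are skipped with a log message.
    """
    genes = list(ctx.genes.index) if genes is None else genes
    frames = []
    snp_ids = ctx.snps.index.to_numpy()
    for gene in genes:
        idx = ctx.cis_snp_indices(gene, window_bp)
        if idx.size == 0:
            logger.info("gene %s has no cis SNPs; skipped", gene)
            continue
        gi = ctx.expression.columns.get_loc(gene)
        beta, se, t, p = marginal_stats(ctx.y_res[:, [gi]], ctx.g_res[:, idx],
                                        ctx.dof)
        frames.append(pd.DataFrame({
            "gene": gene, "snp": snp_ids[idx], "beta": beta[0], "se": se[0],
            "t": t[0], "p": p[0], "n": ctx.n}))
    if not frames:
        return pd.DataFrame(columns=["gene", "snp", "beta", "se", "t", "p", "n"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# eigenMT-style effective number of tests
# ---------------------------------------------------------------------------

def effective_tests(dosages: np.ndarray, var_explained: float = 0.99,
                    chunk: int = 200) -> int:
    """Effective number of independent SNPs in a cis window.

    SNPs are split into consecutive chunks of at most ``chunk``; per chunk
    the count is the minimal number of top eigenvalues of the dosage
    correlation matrix explaining >= ``var_explained`` of total variance.
    Zero-variance SNPs are dropped (each would contribute nothing to the
    correlation matrix). The sum over chunks is capped at the SNP count.
    """
    x = np.asarray(dosages, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("need at least one SNP")
    sd = x.std(axis=0)
    if (sd == 0).any():
        logger.warning("%d zero-variance SNPs dropped from m_eff",
                       int((sd == 0).sum()))
        x = x[:, sd > 0]
        if x.shape[1] == 0:
            return 1
    m = x.shape[1]
    total = 0
    for s in range(0, m, chunk):
        block = x[:, s:s + chunk]
        corr = np.corrcoef(block, rowvar=False)
        corr = np.atleast_2d(corr)
        ev = np.linalg.eigvalsh(corr)[::-1]
        ev = np.clip(ev, 0.0, None)
        cum = np.cumsum(ev) / ev.sum()
        total += int(np.searchsorted(cum, var_explained) + 1)
    return min(total, m)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, monotone q-values)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    reject = q <= alpha
    return reject, q


def hierarchical_correction(min_p: pd.Series, m_eff: pd.Series,
                            fdr: float = 0.05) -> pd.DataFrame:
    """eigenMT-BH: locally adjust per-gene minima, BH across genes, and
    translate the global cutoff into per-gene nominal thresholds.

    ``min_p`` is the per-gene minimum nominal p; ``m_eff`` the per-gene
    effective SNP count. Returns a per-gene frame with p_local, q_global,
    egene flag and nominal_threshold (NaN when no gene is significant).
    """
    genes = min_p.index
    p_local = np.minimum(min_p.to_numpy(float) * m_eff.loc[genes].to_numpy(float),
                         1.0)
    reject, q = bh_fdr(p_local, alpha=fdr)
    if reject.any():
        p_star = float(p_local[reject].max())
        thresholds = p_star / m_eff.loc[genes].to_numpy(float)
    else:
        p_star = np.nan
        thresholds = np.full(len(genes), np.nan)
    return pd.DataFrame({
        "p_local": p_local, "q_global": q, "egene": reject,
        "m_eff": m_eff.loc[genes].to_numpy(), "p_star": p_star,
        "nominal_threshold": thresholds}, index=genes)


def call_egenes(assoc: pd.DataFrame, ctx: ScanContext, fdr: float = 0.05,
                var_explained: float = 0.99, chunk: int = 200,
                window_bp: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """Full per-gene record: m_eff, top SNP, hierarchical correction, eSNPs.

    Top-SNP ties break by smallest p, then largest \\|beta\\|, then smallest
    genomic position, for deterministic output.
    """
    if assoc.empty:
        return pd.DataFrame(columns=[
            "gene", "condition", "m_eff", "top_snp", "top_p", "beta", "se",
            "p_local", "q_global", "egene", "nominal_threshold", "esnps", "n"])
    records = []
    pos = ctx.snps["pos"]
    for gene, sub in assoc.groupby("gene", sort=True):
        idx = ctx.cis_snp_indices(gene, window_bp)
        m_eff = effective_tests(ctx.dosages.to_numpy(float)[:, idx],
                                var_explained=var_explained, chunk=chunk)
        sub = sub.assign(pos=pos.loc[sub["snp"]].to_numpy(),
                         absbeta=sub["beta"].abs())
        sub = sub.sort_values(["p", "absbeta", "pos"],
                              ascending=[True, False, True], kind="stable")
        top = sub.iloc[0]
        records.append({"gene": gene, "condition": ctx.condition,
                        "m_eff": m_eff, "top_snp": top["snp"],
                        "top_p": top["p"], "beta": top["beta"],
                        "se": top["se"], "n": int(top["n"])})
    rec = pd.DataFrame(records).set_index("gene")
    corr = hierarchical_correction(rec["top_p"], rec["m_eff"], fdr=fdr)
    rec = rec.join(corr[["p_local", "q_global", "egene", "p_star",
                         "nominal_threshold"]])
    esnp_lists = []
    for gene, row in rec.iterrows():
        if row["egene"] and np.isfinite(row["nominal_threshold"]):
            sub = assoc[assoc["gene"] == gene]
            hits = sub.loc[sub["p"] <= row["nominal_threshold"], "snp"]
            esnp_lists.append(list(hits))
        else:
            esnp_lists.append([])
    rec["esnps"] = esnp_lists
    return rec.reset_index()


def map_condition(study: ExpressionStudy, panel: GenotypePanel,
                  condition: str, fdr: float = 0.05,
                  window_bp: int = CIS_WINDOW_BP,
                  covariates: pd.DataFrame | None = None
                  ) -> tuple[ScanContext, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: scan one condition and call eGenes."""
    ctx = make_scan_context(study, panel, condition, covariates=covariates)
    assoc = cis_scan(ctx, window_bp=window_bp)
    egenes = call_egenes(assoc, ctx, fdr=fdr, window_bp=window_bp)
    return ctx, assoc, egenes
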