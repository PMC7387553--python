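"""Cross-chromosome (trans) association scan and its three multiple-testing
schemes: genome-wide BH over all pair p-values, gene-level BH on minima
scaled by the genome-wide effective SNP count (1e6 = 0.05 / 5e-8), and a
gene-level Bonferroni threshold of 5e-8 divided by the number of genes.

Only pairs below a storage threshold plus every gene's minimum are kept in
memory; that is sufficient for all three schemes provided the threshold is
no smaller than any rejection boundary in play.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cis import ScanContext, bh_fdr

logger = logging.getLogger("stimeqtl")

GENOME_WIDE_SIG = 5e-8


def genomewide_effective_snps(alpha: float = 0.05,
                              genome_wide_p: float = GENOME_WIDE_SIG) -> float:
    """Estimated number of independent SNPs genome-wide (0.05 / 5e-8 = 1e6)."""
    return alpha / genome_wide_p


def gene_bonferroni_threshold(n_genes: int,
                              genome_wide_p: float = GENOME_WIDE_SIG) -> float:
    """Gene-level Bonferroni cutoff: genome-wide significance over genes."""
    return genome_wide_p / n_genes


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Plain Bonferroni-adjusted p-value threshold."""
    return alpha / n_tests


def trans_scan(ctx: ScanContext, store_p: float = 1e-5) -> pd.DataFrame:
    """OLS for every gene x different-chromosome SNP pair.

    Returns rows with p < ``store_p`` plus each gene's minimum (flagged by
    ``is_gene_min``), along with the total number of tests performed,
    stored in ``attrs['n_tests']`` for the genome-wide scheme.
    """
    gene_chrom = ctx.genes.loc[ctx.expression.columns, "chrom"].to_numpy()
    snp_chrom = ctx.snps["chrom"].to_numpy()
    snp_ids = ctx.snps.index.to_numpy()
    syy = (ctx.y_res ** 2).sum(axis=0)
    sgg = (ctx.g_res ** 2).sum(axis=0)
    dof = ctx.dof

    frames = []
    n_tests = 0
    gene_ids = ctx.expression.columns.to_numpy()
    for chrom in np.unique(gene_chrom):
        gsel = np.flatnonzero(gene_chrom == chrom)
        ssel = np.flatnonzero(snp_chrom != chrom)
        if gsel.size == 0 or ssel.size == 0:
            continue
        n_tests += gsel.size * ssel.size
        sxy = ctx.y_res[:, gsel].T @ ctx.g_res[:, ssel]
        beta = sxy / sgg[ssel][None, :]
        rss = np.clip(syy[gsel][:, None] - beta ** 2 * sgg[ssel][None, :],
                      0.0, None)
        se = np.sqrt(rss / dof / sgg[ssel][None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df=dof)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        keep = p < store_p
        gene_min = p.argmin(axis=1)
        keep[np.arange(len(gsel)), gene_min] = True
        gi, sj = np.nonzero(keep)
        frames.append(pd.DataFrame({
            "gene": gene_ids[gsel][gi], "snp": snp_ids[ssel][sj],
            "beta": beta[gi, sj], "se": se[gi, sj], "t": t[gi, sj],
            "p": p[gi, sj],
            "is_gene_min": sj == gene_min[gi]}))
    out = (pd.concat(frames, ignore_index=True) if frames else
           pd.DataFrame(columns=["gene", "snp", "beta", "se", "t", "p",
                                 "is_gene_min"]))
    out.attrs["n_tests"] = n_tests
    out.attrs["condition"] = ctx.condition
    return out


def trans_multiple_testing(results: pd.DataFrame, n_genes: int,
                           fdr: float = 0.05) -> pd.DataFrame:
    """Apply the three correction schemes; adds three boolean flag columns.

    Scheme 1 (genome-wide FDR): BH over all pair p-values, where unstored
    pairs (p >= the storage threshold) are counted in the total test
    number — valid because no rejection boundary can exceed the storage
    threshold at any realistic scan size.
    Scheme 2 (gene-level FDR): per-gene min p times 1e6 (capped at 1), BH
    over genes.
    Scheme 3 (gene-level Bonferroni): per-gene min p below 5e-8 / n_genes.
    """
    out = results.copy()
    if out.empty:
        for col in ("genomewide_fdr_sig", "genelevel_fdr_sig",
                    "genelevel_bonf_sig"):
            out[col] = []
        return out
    n_tests = int(results.attrs.get("n_tests", len(results)))

    # scheme 1: BH step-up with the full test count as m
    p = out["p"].to_numpy()
    order = np.argsort(p, kind="stable")
    thresholds = fdr * np.arange(1, len(p) + 1) / n_tests
    passing = np.flatnonzero(p[order] <= thresholds)
    cutoff = p[order][passing.max()] if passing.size else -1.0
    out["genomewide_fdr_sig"] = p <= cutoff

    # schemes 2 and 3 act on per-gene minima
    mins = out[out["is_gene_min"]].set_index("gene")["p"]
    adj = np.minimum(mins.to_numpy() * genomewide_effective_snps(), 1.0)
    # genes whose minimum was not stored are null here; count them in BH m
    m_total = n_genes
    order2 = np.argsort(adj, kind="stable")
    thr2 = fdr * np.arange(1, len(adj) + 1) / m_total
    passing2 = np.flatnonzero(adj[order2] <= thr2)
    cut2 = adj[order2][passing2.max()] if passing2.size else -1.0
    gene_sig2 = pd.Series(adj <= cut2, index=mins.index)
    gene_sig3 = pd.Series(mins.to_numpy() < gene_bonferroni_threshold(n_genes),
                          index=mins.index)

    min_snp = out[out["is_gene_min"]].set_index("gene")["snp"]
    key = pd.MultiIndex.from_frame(out[["gene", "snp"]])
    gene_min_key = set(zip(min_snp.index, min_snp))
    is_min = pd.Series([k in gene_min_key for k in key], index=out.index)
    out["genelevel_fdr_sig"] = is_min.to_numpy() & \
        out["gene"].map(gene_sig2).fillna(False).to_numpy()
    out["genelevel_bonf_sig"] = is_min.to_numpy() & \
        out["gene"].map(gene_sig3).fillna(False).to_numpy()
    out.attrs.update(results.attrs)
    return out


def link_trans_to_cis(trans_hits: pd.DataFrame, egenes: pd.DataFrame,
                      panel=None, proxy_r2: float | None = 0.8
                      ) -> pd.DataFrame:
    """Trios (snp, cis gene, trans gene) where a trans-eSNP is also a
    significant cis-eSNP for a local gene.

    With ``proxy_r2`` set and a panel available, a trans-eSNP also links
    through any cis-eSNP in LD at r^2 >= proxy_r2; with ``proxy_r2=None``
    only exact SNP-id matches link.
    """
    rows = []
    cis_pairs = []
    for _, erow in egenes[egenes["egene"]].iterrows():
        for esnp in erow["esnps"]:
            cis_pairs.append((esnp, erow["gene"]))
    for _, hit in trans_hits.iterrows():
        for esnp, cis_gene in cis_pairs:
            match = esnp == hit["snp"]
            if not match and proxy_r2 is not None and panel is not None:
                match = panel.ld_r2(esnp, hit["snp"]) >= proxy_r2
            if match:
                rows.append({"snp": hit["snp"], "cis_snp": esnp,
                             "cis_gene": cis_gene, "trans_gene": hit["gene"]})
    return pd.DataFrame(rows, columns=["snp", "cis_snp", "cis_gene",
                                       "trans_gene"]).drop_duplicates(
        ["snp", "cis_gene", "trans_gene"]).reset_index(drop=True)
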