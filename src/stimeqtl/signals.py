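"""Conditional dissection of independent cis-eQTL signals.

Forward stage: iteratively re-scan a gene's cis window while conditioning
on all previously selected SNPs (added to the covariates), selecting the
new top SNP while anything stays below the gene's nominal threshold from
the hierarchical correction. Backward stage: each selected SNP is
re-tested in a leave-one-out model conditioning on all the others; only
signals that stay significant are kept. Cross-condition conditioning uses
the same machinery to label a gene's eQTL in two conditions as independent
or shared (the latter explicitly "shared or underpowered").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cis import ScanContext, marginal_stats, residualise, CIS_WINDOW_BP

logger = logging.getLogger("stimeqtl")


@dataclass
class SignalSet:
    """Independent eQTL signals for one gene in one condition."""

    gene: str
    condition: str
    snps: list[str]
    stats: pd.DataFrame  # per-signal snp, beta, se, t, p (leave-one-out model)

    @property
    def n_signals(self) -> int:
        return len(self.snps)


def _conditional_scan(ctx: ScanContext, gene: str, conditioning: list[str],
                      window_bp: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """Scan a gene's cis window conditioning on the given SNPs' dosages.

    Candidates collinear with the conditioning set (r^2 = 1 after
    residualisation) are excluded. Returns per-candidate stats sorted by
    the deterministic top-SNP tie rule.
    """
    idx = ctx.cis_snp_indices(gene, window_bp)
    snp_ids = ctx.snps.index.to_numpy()[idx]
    cand_mask = ~np.isin(snp_ids, conditioning)
    if not cand_mask.any():
        return pd.DataFrame(columns=["snp", "beta", "se", "t", "p"])
    cond_dos = ctx.dosages[conditioning].to_numpy(float) if conditioning \
        else np.empty((ctx.n, 0))
    covs = np.column_stack([ctx.covariates, cond_dos]) if cond_dos.size \
        else ctx.covariates
    gi = ctx.expression.columns.get_loc(gene)
    y_res = residualise(ctx.expression.to_numpy(float)[:, [gi]], covs)
    g_res = residualise(ctx.dosages.to_numpy(float)[:, idx[cand_mask]], covs)
    dof = ctx.n - covs.shape[1] - 2
    # drop candidates absorbed by the conditioning set
    keep = g_res.std(axis=0) > 1e-10 * ctx.dosages.to_numpy(float)[
        :, idx[cand_mask]].std(axis=0).clip(min=1e-12)
    if not keep.all():
        logger.info("%d collinear candidates excluded for %s",
                    int((~keep).sum()), gene)
    if not keep.any():
        return pd.DataFrame(columns=["snp", "beta", "se", "t", "p"])
    beta, se, t, p = marginal_stats(y_res, g_res[:, keep], dof)
    out = pd.DataFrame({"snp": snp_ids[cand_mask][keep], "beta": beta[0],
                        "se": se[0], "t": t[0], "p": p[0]})
    out["pos"] = ctx.snps.loc[out["snp"], "pos"].to_numpy()
    out["absbeta"] = out["beta"].abs()
    return out.sort_values(["p", "absbeta", "pos"],
                           ascending=[True, False, True],
                           kind="stable").drop(columns=["pos", "absbeta"])


def forward_stage(ctx: ScanContext, gene: str, top_snp: str,
                  nominal_threshold: float, max_signals: int = 10,
                  window_bp: int = CIS_WINDOW_BP) -> list[str]:
    """Ordered list of independent signal SNPs for an eGene.

    Starts from the marginal top SNP; each iteration conditions on all
    selected SNPs and adds the new top SNP while its p stays below the
    gene's nominal threshold.
    """
    if not np.isfinite(nominal_threshold):
        raise ValueError(f"{gene}: nominal threshold undefined (not an eGene)")
    selected = [top_snp]
    while len(selected) < max_signals:
        scan = _conditional_scan(ctx, gene, selected, window_bp)
        if scan.empty or scan.iloc[0]["p"] >= nominal_threshold:
            break
        selected.append(scan.iloc[0]["snp"])
    return selected


def backward_stage(ctx: ScanContext, gene: str, forward: list[str],
                   nominal_threshold: float,
                   window_bp: int = CIS_WINDOW_BP) -> SignalSet:
    """Leave-one-out re-test of each forward signal; keep the survivors.

    Signal i is represented by the top SNP of the cis re-scan that
    conditions on all other selected SNPs; it is retained iff that top p
    is below the gene's nominal threshold.
    """
    kept_rows = []
    for i, snp in enumerate(forward):
        others = [s for j, s in enumerate(forward) if j != i]
        scan = _conditional_scan(ctx, gene, others, window_bp)
        if scan.empty:
            continue
        top = scan.iloc[0]
        if top["p"] < nominal_threshold:
            kept_rows.append({"signal_rank": i + 1, "snp": top["snp"],
                              "beta": top["beta"], "se": top["se"],
                              "t": top["t"], "p": top["p"]})
    stats_df = pd.DataFrame(kept_rows,
                            columns=["signal_rank", "snp", "beta", "se",
                                     "t", "p"])
    return SignalSet(gene=gene, condition=ctx.condition,
                     snps=list(stats_df["snp"]), stats=stats_df)


def dissect_gene(ctx: ScanContext, gene: str, top_snp: str,
                 nominal_threshold: float, max_signals: int = 10,
                 window_bp: int = CIS_WINDOW_BP) -> SignalSet:
    forward = forward_stage(ctx, gene, top_snp, nominal_threshold,
                            max_signals, window_bp)
    return backward_stage(ctx, gene, forward, nominal_threshold, window_bp)


def cross_condition_conditioning(ctx_b: ScanContext, gene: str,
                                 top_esnp_a: str, nominal_threshold_b: float,
                                 window_bp: int = CIS_WINDOW_BP) -> str:
    """Classify a gene's eQTL in condition B against condition A's top eSNP.

    Re-scans condition B's cis window conditioning on A's top eSNP:
    "independent" iff any SNP stays below B's nominal threshold, otherwise
    "shared" (which, as the design acknowledges, cannot be distinguished
    from lack of power to detect an independent signal).
    """
    if top_esnp_a not in ctx_b.dosages.columns:
        raise KeyError(f"conditioning SNP {top_esnp_a} absent from panel")
    scan = _conditional_scan(ctx_b, gene, [top_esnp_a], window_bp)
    if not scan.empty and scan.iloc[0]["p"] < nominal_threshold_b:
        return "independent"
    return "shared"


def classify_condition_pairs(contexts: dict[str, ScanContext],
                             egenes: dict[str, pd.DataFrame],
                             window_bp: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """Cross-condition verdicts for every gene significant in two
    conditions, computed in both directions."""
    rows = []
    conds = list(contexts)
    for i, ca in enumerate(conds):
        for cb in conds[i + 1:]:
            ea = egenes[ca].set_index("gene")
            eb = egenes[cb].set_index("gene")
            both = ea.index[ea["egene"]].intersection(eb.index[eb["egene"]])
            for gene in both:
                v_ab = cross_condition_conditioning(
                    contexts[cb], gene, ea.loc[gene, "top_snp"],
                    eb.loc[gene, "nominal_threshold"], window_bp)
                v_ba = cross_condition_conditioning(
                    contexts[ca], gene, eb.loc[gene, "top_snp"],
                    ea.loc[gene, "nominal_threshold"], window_bp)
                rows.append({"gene": gene, "cond_a": ca, "cond_b": cb,
                             "verdict_a_on_b": v_ab, "verdict_b_on_a": v_ba})
    return pd.DataFrame(rows, columns=["gene", "cond_a", "cond_b",
                                       "verdict_a_on_b", "verdict_b_on_a"])
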