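"""Genotype QC and the expression normalisation/filtering pipeline.

The expression path assumes background-corrected, positive intensities
(microarray negative-control correction is out of scope here); the fixed
order is: sample QC -> probe filters -> probe-per-gene selection ->
within-condition quantile normalisation + log2 -> per-analysis rank-based
inverse normal transform.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypePanel, compute_maf

logger = logging.getLogger("stimeqtl")


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def hwe_chisq_p(counts_hom_ref: int, counts_het: int, counts_hom_alt: int) -> float:
    """Hardy-Weinberg 1-d.f. chi-square p from hard genotype counts."""
    n = counts_hom_ref + counts_het + counts_hom_alt
    if n == 0:
        return 1.0
    p = (2 * counts_hom_ref + counts_het) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([counts_hom_ref, counts_het, counts_hom_alt], dtype=float)
    nz = exp > 0
    chi2 = ((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum()
    return float(stats.chi2.sf(chi2, df=1))


def genotype_qc(panel: GenotypePanel, max_missing: float = 0.01,
                min_maf: float = 0.01, hwe_p_min: float = 1e-6) -> GenotypePanel:
    """Drop SNPs failing call rate, MAF or Hardy-Weinberg filters.

    Missing call rate is the NaN fraction per SNP (removed when
    > ``max_missing``); MAF below ``min_maf`` is removed; HWE uses a 1-d.f.
    chi-square on dosages rounded to hard calls, removed when
    p < ``hwe_p_min``.
    """
    dos = panel.dosages.to_numpy(float)
    if dos.shape[1] == 0:
        return panel
    miss = np.isnan(dos).mean(axis=0)
    maf = compute_maf(dos)
    hard = np.rint(dos)
    hwe = np.empty(dos.shape[1])
    for j in range(dos.shape[1]):
        col = hard[~np.isnan(hard[:, j]), j]
        hwe[j] = hwe_chisq_p(int((col == 0).sum()), int((col == 1).sum()),
                             int((col == 2).sum()))
    keep = (miss <= max_missing) & (maf >= min_maf) & (hwe >= hwe_p_min)
    if not keep.any():
        logger.warning("genotype_qc removed every SNP")
    kept = panel.subset(panel.snps.index[keep])
    return kept.refresh_maf()


def analysis_maf_filter(panel: GenotypePanel, min_maf: float = 0.10) -> GenotypePanel:
    """Keep SNPs with MAF >= min_maf (the analysis-stage frequency floor)."""
    if panel.n_snps == 0:
        return panel
    maf = compute_maf(panel.dosages.to_numpy(float))
    return panel.subset(panel.snps.index[maf >= min_maf])


# ---------------------------------------------------------------------------
# expression filters
# ---------------------------------------------------------------------------

def detectability_filter(detection_p: pd.DataFrame, condition: pd.Series,
                         cond_frac: float = 0.025, all_frac: float = 0.05,
                         p_thresh: float = 0.01) -> pd.Index:
    """Keep genes detected (p <= p_thresh) in >= ``cond_frac`` of any one
    condition's samples OR >= ``all_frac`` of all samples.

    ``detection_p`` is samples x genes; ``condition`` labels each sample.
    Missing detection p-values count as undetected.
    """
    dp = detection_p.to_numpy(float)
    n_missing = int(np.isnan(dp).sum())
    if n_missing:
        logger.warning("%d missing detection p-values treated as undetected",
                       n_missing)
    detected = np.nan_to_num(dp, nan=1.0) <= p_thresh
    cond = condition.loc[detection_p.index]
    keep = np.zeros(detection_p.shape[1], dtype=bool)
    for c in cond.unique():
        mask = (cond == c).to_numpy()
        keep |= detected[mask].mean(axis=0) >= cond_frac
    keep |= detected.mean(axis=0) >= all_frac
    return detection_p.columns[keep]


def select_probe_per_gene(matrix: pd.DataFrame,
                          probe_to_gene: pd.Series) -> pd.DataFrame:
    """Per gene keep the probe with the highest mean intensity.

    Ties break to the lexicographically smallest probe id. Returns the
    samples x genes matrix (columns renamed to gene ids).
    """
    table = pd.DataFrame({
        "probe": matrix.columns,
        "gene": probe_to_gene.loc[matrix.columns].to_numpy(),
        "mean": matrix.mean(axis=0).to_numpy(),
    })
    table = table.sort_values(["gene", "mean", "probe"],
                              ascending=[True, False, True])
    best = table.groupby("gene", sort=True).head(1)
    out = matrix.loc[:, best["probe"]]
    out.columns = best["gene"].to_numpy()
    return out


def probe_missingness_filter(matrix: pd.DataFrame,
                             max_missing_samples: int = 5) -> pd.DataFrame:
    """Drop probes with missing data in >= ``max_missing_samples`` samples."""
    n_missing = matrix.isna().sum(axis=0)
    return matrix.loc[:, n_missing < max_missing_samples]


def outlier_sample_filter(detectable_counts: pd.Series) -> pd.Index:
    """Keep samples whose detectable-probe count lies inside
    median +/- 2 * IQR."""
    med = detectable_counts.median()
    q1, q3 = detectable_counts.quantile([0.25, 0.75])
    iqr = q3 - q1
    keep = (detectable_counts >= med - 2 * iqr) & \
           (detectable_counts <= med + 2 * iqr)
    return detectable_counts.index[keep]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def quantile_normalise_log2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise each sample (row) to the cross-sample mean
    quantile distribution, then log2.

    Ties within a sample receive the mean of the reference values at the
    tied ranks. Inputs must be positive (background-corrected) intensities.
    """
    x = matrix.to_numpy(float)
    if np.any(x <= 0):
        raise ValueError("quantile normalisation requires positive intensities")
    order = np.sort(x, axis=1)
    reference = order.mean(axis=0)
    ranks = np.apply_along_axis(stats.rankdata, 1, x)  # average ranks for ties
    # interpolate reference at (possibly fractional) average ranks
    out = np.interp(ranks, np.arange(1, x.shape[1] + 1), reference)
    return pd.DataFrame(np.log2(out), index=matrix.index,
                        columns=matrix.columns)


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset by default).

    Maps values to ``Phi^-1((r - c) / (n + 1 - 2c))`` with average ranks
    for ties. Fails on constant input (no ranking possible).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expects a 1-D vector")
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    if np.nanstd(v) == 0:
        raise ValueError("constant vector cannot be rank-transformed")
    r = stats.rankdata(v)
    return stats.norm.ppf((r - offset) / (v.size + 1 - 2 * offset))


def int_transform_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply the inverse normal transform to each gene (column)."""
    out = np.empty(matrix.shape)
    x = matrix.to_numpy(float)
    for j in range(x.shape[1]):
        out[:, j] = inverse_normal_transform(x[:, j])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def expression_pcs(matrix: pd.DataFrame, n_components: int = 10) -> pd.DataFrame:
    """Top principal components of a samples x genes matrix.

    Used as latent technical-variation covariates (the deterministic
    stand-in for per-condition latent-factor inference). Components are
    unit-variance scores with a sign convention (largest-|loading| gene
    positive) for reproducibility.
    """
    x = matrix.to_numpy(float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * np.sqrt(x.shape[0] - 1)
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=matrix.index,
                        columns=[f"PC{i+1}" for i in range(k)])
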