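"""Shared simulation scenarios for recovery and calibration tests.

The "unit-variance" configuration keeps the raw expression scale near one
standard deviation so that planted betas stated in s.d./allele are on the
scale the scan estimates (the rank-based INT preserves that scale when
the raw distribution is already close to normal with unit variance).
"""

import numpy as np
import pandas as pd

import stimeqtl as sq


def unit_variance_cfg(seed: int, n_individuals: int = 120, n_genes: int = 40,
                      n_snps: int = 400, **overrides) -> sq.SimConfig:
    defaults = dict(
        n_individuals=n_individuals, n_genes=n_genes, n_snps=n_snps,
        n_cis_eqtls=0, n_reqtls=0, n_signflip_reqtls=0, n_trans_trios=0,
        n_causal_genes=0, n_gwas_loci_shared=0, n_gwas_loci_distinct=0,
        retention=(1.0, 1.0, 1.0, 1.0),
        maf_range=(0.30, 0.30),
        noise_sd=0.8, individual_re_sd=0.3, covariate_effect_sd=0.1,
        condition_effect_sd=0.0, seed=seed)
    defaults.update(overrides)
    return sq.SimConfig(**defaults)


def plant_fixed_cis(panel: sq.GenotypePanel, cfg: sq.SimConfig, beta: float,
                    n_effects: int, beta_stim: float | None = None,
                    cell_type: str = "t") -> sq.TruthTable:
    """Truth table with exact betas on the first genes with cis SNPs."""
    genes = sq.gene_annotation(panel, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for gene, g in genes.iterrows():
        window = panel.snps[(panel.snps["chrom"] == g["chrom"]) &
                            (abs(panel.snps["pos"] - g["tss"]) <= 1_000_000)]
        if window.empty:
            continue
        snp = window.index[rng.integers(len(window))]
        rows.append({"gene": gene, "snp": snp, "cell_type": cell_type,
                     "beta_resting": beta,
                     "beta_stimulated": beta if beta_stim is None
                     else beta_stim})
        if len(rows) == n_effects:
            break
    empty_trans = pd.DataFrame(columns=["snp", "cis_gene", "trans_gene", "a",
                                        "b", "c_prime", "cell_type",
                                        "condition"])
    empty_loci = pd.DataFrame(columns=["locus", "causal_snp", "eqtl_gene",
                                       "eqtl_snp", "shared_with_eqtl"])
    empty_causal = pd.DataFrame(columns=["gene", "disease", "effect"])
    return sq.TruthTable(cis=pd.DataFrame(rows), trans=empty_trans,
                         gwas_loci=empty_loci, causal_genes=empty_causal)


def null_truth() -> sq.TruthTable:
    return sq.TruthTable(
        cis=pd.DataFrame(columns=["gene", "snp", "cell_type",
                                  "beta_resting", "beta_stimulated"]),
        trans=pd.DataFrame(columns=["snp", "cis_gene", "trans_gene", "a",
                                    "b", "c_prime", "cell_type",
                                    "condition"]),
        gwas_loci=pd.DataFrame(columns=["locus", "causal_snp", "eqtl_gene",
                                        "eqtl_snp", "shared_with_eqtl"]),
        causal_genes=pd.DataFrame(columns=["gene", "disease", "effect"]))
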