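import numpy as np
import pandas as pd
import pytest

import stimeqtl as sq


@pytest.fixture(scope="session")
def small_cfg():
    return sq.SimConfig(n_individuals=120, n_genes=40, n_snps=400,
                        n_cis_eqtls=10, n_reqtls=4, n_signflip_reqtls=2,
                        n_trans_trios=1, n_gwas_loci_shared=1,
                        n_gwas_loci_distinct=1, n_causal_genes=1,
                        seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    """One simulated study reused across read-only tests."""
    panel, study, truth, gwas = sq.simulate_study(small_cfg, n_gwas=4000)
    return {"panel": panel, "study": study, "truth": truth, "gwas": gwas,
            "cfg": small_cfg}


def make_panel(dosages: np.ndarray, chrom=None, pos=None) -> sq.GenotypePanel:
    """Hand-built panel from a raw dosage matrix."""
    n, m = dosages.shape
    snp_ids = pd.Index([f"s{j}" for j in range(m)], name="snp")
    snps = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "ref": "A", "alt": "G",
        "maf": sq.compute_maf(dosages)}, index=snp_ids)
    dos = pd.DataFrame(dosages,
                       index=pd.Index([f"i{i}" for i in range(n)],
                                      name="individual"),
                       columns=snp_ids)
    return sq.GenotypePanel(dos, snps)
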