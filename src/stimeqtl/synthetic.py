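"""Synthetic paired-condition eQTL study generator.

Emulates a cord-blood immune stimulation design: four experimental
conditions (resting/LPS myeloid cells, resting/PHA T cells) measured on a
shared set of individuals, genotypes in LD blocks with MAF >= 10%, planted
cis-eQTLs and response-eQTLs (including sign flips), cis-mediated trans
effects, GWAS loci that do or do not share causal variants with eQTLs, and
genes with true causal effects on a disease liability.

LD is produced by a Gaussian copula: two independent haplotype draws from a
latent Markov-chain normal per block, thresholded at the Hardy-Weinberg
quantile of each SNP's allele frequency. The latent adjacent correlation is
solved numerically (tetrachoric inversion) so the *dosage* correlation hits
the configured target despite threshold attenuation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .data import GenotypePanel, ExpressionStudy, compute_maf

logger = logging.getLogger("stimeqtl")

#: canonical condition labels: (cell type, treatment)
DEFAULT_CONDITIONS = [
    ("myeloid", "resting"),
    ("myeloid", "lps"),
    ("t", "resting"),
    ("t", "pha"),
]

#: per-condition post-QC sample retention emulating 116/125/126/127 of 135
DEFAULT_RETENTION = (116 / 135, 125 / 135, 126 / 135, 127 / 135)


def condition_label(cell_type: str, treatment: str) -> str:
    return f"{cell_type}_{treatment}"


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 135 genotyped individuals with
    unequal per-condition retention, a shared core subset present in all
    four conditions, SNPs in LD blocks with generating MAF in [0.10, 0.50],
    and 14 covariates (sex, three genotype-PC proxies, ten latent factors).
    """

    n_individuals: int = 135
    conditions: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_CONDITIONS))
    retention: tuple[float, ...] = DEFAULT_RETENTION
    core_fraction: float = 95 / 135
    n_genes: int = 300
    n_snps: int = 3000
    n_chromosomes: int = 4
    snp_spacing_bp: int = 5_000
    ld_block_size: int = 20
    within_block_r: float = 0.6
    maf_range: tuple[float, float] = (0.10, 0.50)
    n_cis_eqtls: int = 60
    n_reqtls: int = 20
    n_signflip_reqtls: int = 4
    n_trans_trios: int = 3
    n_gwas_loci_shared: int = 2
    n_gwas_loci_distinct: int = 2
    n_causal_genes: int = 2
    ivs_per_causal_gene: int = 4
    causal_gene_eqtl_beta: float = 1.0
    effect_size_sd: float = 0.8
    condition_effect_sd: float = 0.5
    covariate_effect_sd: float = 0.15
    individual_re_sd: float = 0.5
    noise_sd: float = 1.0
    n_covariates: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.10 <= lo <= hi <= 0.50):
            raise ValueError("maf_range must lie within [0.10, 0.50]")
        if len(self.retention) != len(self.conditions):
            raise ValueError("one retention fraction per condition required")
        if any(not (0 < f <= 1) for f in self.retention):
            raise ValueError("retention fractions must be in (0, 1]")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must be in [0, 1)")
        for name in ("n_individuals", "n_genes", "n_snps", "n_cis_eqtls",
                     "n_reqtls", "n_signflip_reqtls", "n_trans_trios"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_signflip_reqtls > self.n_reqtls:
            raise ValueError("n_signflip_reqtls cannot exceed n_reqtls")
        if self.n_covariates != 14:
            raise ValueError("the covariate design is fixed at 14 columns")

    @property
    def condition_labels(self) -> list[str]:
        return [condition_label(ct, tr) for ct, tr in self.conditions]

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-scoped RNG split from the global seed (crc32 keeps the
        split deterministic across processes, unlike builtin hash)."""
        key = zlib.crc32(stage.encode()) % 2**31
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class TruthTable:
    """Ground truth of all planted effects, for recovery tests."""

    cis: pd.DataFrame      # gene, snp, cell_type, beta_resting, beta_stimulated
    trans: pd.DataFrame    # snp, cis_gene, trans_gene, a, b, c_prime, condition
    gwas_loci: pd.DataFrame   # locus, causal_snp, eqtl_gene, shared_with_eqtl
    causal_genes: pd.DataFrame  # gene, disease, effect

    def validate(self, panel: GenotypePanel, genes: pd.Index) -> None:
        for frame, col, universe, what in [
                (self.cis, "snp", panel.snps.index, "SNP"),
                (self.cis, "gene", genes, "gene"),
                (self.trans, "snp", panel.snps.index, "SNP"),
                (self.trans, "cis_gene", genes, "gene"),
                (self.trans, "trans_gene", genes, "gene"),
                (self.gwas_loci, "causal_snp", panel.snps.index, "SNP"),
                (self.causal_genes, "gene", genes, "gene")]:
            if len(frame):
                missing = set(frame[col]) - set(universe)
                if missing:
                    raise KeyError(
                        f"truth table references unknown {what}: {sorted(missing)[0]}")
        flips = self.cis[self.cis["beta_resting"] * self.cis["beta_stimulated"] < 0]
        # sign-flip invariant is structural; nothing to enforce beyond existence
        _ = flips

    def to_json(self, path) -> None:
        payload = {name: getattr(self, name).to_dict(orient="records")
                   for name in ("cis", "trans", "gwas_loci", "causal_genes")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: pd.DataFrame(v) for k, v in payload.items()})


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _dosage_corr_from_latent(rho: float, p1: float, p2: float) -> float:
    """Pearson correlation of thresholded-allele dosages at latent corr rho."""
    if rho == 0.0:
        return 0.0
    z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    p11 = stats.multivariate_normal.cdf(
        [z1, z2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return float((p11 - p1 * p2) / denom)


def _latent_rho(target_r: float, p1: float, p2: float) -> float:
    """Invert the copula attenuation: latent rho giving dosage corr target_r."""
    if target_r <= 0.0:
        return 0.0
    hi = 0.9999
    if _dosage_corr_from_latent(hi, p1, p2) <= target_r:
        return hi
    return brentq(lambda r: _dosage_corr_from_latent(r, p1, p2) - target_r,
                  0.0, hi, xtol=1e-4)


def _draw_block_haplotypes(rng, n_hap: int, mafs: np.ndarray,
                           rho: float) -> np.ndarray:
    """(n_hap x block) allele matrix from a latent Markov chain."""
    m = len(mafs)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    w = np.sqrt(1.0 - rho ** 2)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + w * rng.standard_normal(n_hap)
    return (z < stats.norm.ppf(mafs)[None, :]).astype(np.int8)


def _draw_dosages(rng, n: int, mafs: np.ndarray, blocks: list[np.ndarray],
                  latent_rhos: np.ndarray) -> np.ndarray:
    """(n x m) dosage matrix; two independent haplotypes per individual."""
    out = np.empty((n, len(mafs)), dtype=np.int8)
    for b, idx in enumerate(blocks):
        h1 = _draw_block_haplotypes(rng, n, mafs[idx], latent_rhos[b])
        h2 = _draw_block_haplotypes(rng, n, mafs[idx], latent_rhos[b])
        out[:, idx] = h1 + h2
    return out


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Simulate an LD-blocked biallelic SNP panel for cfg.n_individuals.

    Monomorphic SNPs after sampling are re-drawn i.i.d. from their
    generating frequency (and logged); all generating MAFs respect the
    configured floor.
    """
    rng = cfg.rng("genotypes")
    m, n = cfg.n_snps, cfg.n_individuals
    if m == 0:
        empty = pd.DataFrame(np.empty((n, 0)),
                             index=pd.Index([f"ind{i:04d}" for i in range(n)],
                                            name="individual"))
        snps = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "maf"])
        return GenotypePanel(empty, snps)

    blocks = [np.arange(s, min(s + cfg.ld_block_size, m))
              for s in range(0, m, cfg.ld_block_size)]
    # SNPs in strong LD have similar allele frequencies: draw a block-level
    # MAF and jitter per SNP (keeps the copula's target correlation
    # attainable; wildly unequal frequencies cap the Pearson r of binaries)
    lo, hi = cfg.maf_range
    mafs = np.empty(m)
    for idx in blocks:
        base = rng.uniform(lo, hi)
        mafs[idx] = np.clip(base + rng.normal(0, 0.02, size=len(idx)), lo, hi)
    latent_rhos = np.array([
        _latent_rho(cfg.within_block_r, float(mafs[idx].mean()),
                    float(mafs[idx].mean()))
        for idx in blocks])

    dos = _draw_dosages(rng, n, mafs, blocks, latent_rhos)
    # resample monomorphic columns (rare at MAF >= 0.10 unless n is tiny)
    for j in np.flatnonzero(dos.std(axis=0) == 0):
        logger.warning("monomorphic SNP %d resampled", j)
        while dos[:, j].std() == 0:
            dos[:, j] = rng.binomial(2, mafs[j], size=n)

    per_chrom = int(np.ceil(m / cfg.n_chromosomes))
    chrom = np.array([f"chr{j // per_chrom + 1}" for j in range(m)])
    pos = np.array([(j % per_chrom) * cfg.snp_spacing_bp + 1
                    for j in range(m)])
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    alt = np.array([bases[(list(bases).index(r) + 1 + rng.integers(0, 3)) % 4]
                    for r in ref])

    snp_ids = pd.Index([f"snp{j:05d}" for j in range(m)], name="snp")
    dosages = pd.DataFrame(dos.astype(float),
                           index=pd.Index([f"ind{i:04d}" for i in range(n)],
                                          name="individual"),
                           columns=snp_ids)
    snps = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                         "maf": compute_maf(dos)}, index=snp_ids)
    sim = {"mafs": mafs, "blocks": blocks, "latent_rhos": latent_rhos,
           "generating_maf": mafs}
    return GenotypePanel(dosages, snps, sim=sim)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

def plant_truth(panel: GenotypePanel, cfg: SimConfig,
                gene_ids: pd.Index | None = None) -> TruthTable:
    """Assign planted effects to concrete genes and SNPs.

    Genes are laid out at regular TSS spacing across the panel's
    chromosomes. Planted cis SNPs are drawn from each gene's 1-Mb window;
    each effect belongs to one cell type. The first ``n_reqtls`` planted
    pairs get condition-dependent slopes; of these the first
    ``n_signflip_reqtls`` flip sign on stimulation. MR-causal genes receive
    several causal cis SNPs in distinct LD blocks so that pruned
    instruments remain.
    """
    rng = cfg.rng("truth")
    genes = _gene_table(panel, cfg) if gene_ids is None else None
    if genes is None:
        raise ValueError("gene annotation must come from _gene_table")
    gene_idx = genes.index

    snp_pos = panel.snps["pos"].to_numpy()
    snp_chrom = panel.snps["chrom"].to_numpy()
    snp_ids = panel.snps.index.to_numpy()
    block_of = np.arange(len(snp_ids)) // max(cfg.ld_block_size, 1)

    def cis_snps_of(gene: str) -> np.ndarray:
        g = genes.loc[gene]
        mask = (snp_chrom == g["chrom"]) & (np.abs(snp_pos - g["tss"]) <= 1_000_000)
        return np.flatnonzero(mask)

    cell_types = sorted({ct for ct, _ in cfg.conditions})
    usable = [g for g in gene_idx if len(cis_snps_of(g)) > 0]
    rng.shuffle(usable)

    records = []
    reserved = 2 * cfg.n_trans_trios + cfg.n_causal_genes
    n_cis = min(cfg.n_cis_eqtls, max(len(usable) - reserved, 0))
    for k in range(n_cis):
        gene = usable[k]
        j = int(rng.choice(cis_snps_of(gene)))
        mag = abs(rng.normal(cfg.effect_size_sd, cfg.effect_size_sd / 6))
        sign = rng.choice([-1.0, 1.0])
        beta_rest = sign * mag
        if k < cfg.n_signflip_reqtls:
            beta_stim = -beta_rest
        elif k < cfg.n_reqtls:
            delta = rng.choice([-1.0, 1.0]) * abs(rng.normal(0.6, 0.1))
            beta_stim = beta_rest + delta
        else:
            beta_stim = beta_rest
        records.append({"gene": gene, "snp": snp_ids[j],
                        "cell_type": cell_types[k % len(cell_types)],
                        "beta_resting": beta_rest, "beta_stimulated": beta_stim})
    cis = pd.DataFrame(records,
                       columns=["gene", "snp", "cell_type",
                                "beta_resting", "beta_stimulated"])

    # --- trans trios: snp -> cis gene (mediator) -> trans gene ------------
    trans_records = []
    pool = [g for g in usable[n_cis:] if len(cis_snps_of(g)) > 0]
    stim_label = {"myeloid": "lps", "t": "pha"}
    for k in range(cfg.n_trans_trios):
        if len(pool) < 2 or not len(cis):
            break
        mediator = pool.pop()
        j = int(rng.choice(cis_snps_of(mediator)))
        snp = snp_ids[j]
        other_chrom = [g for g in pool
                       if genes.loc[g, "chrom"] != panel.snps.loc[snp, "chrom"]]
        if not other_chrom:
            break
        trans_gene = other_chrom[-1]
        pool.remove(trans_gene)
        # strong mediator chain: detected trans signals are the extreme
        # tail of real scans, so planted trios sit well above the
        # genome-wide threshold at n ~ 120
        a = abs(rng.normal(2.0 * cfg.effect_size_sd, cfg.effect_size_sd / 8))
        b = abs(rng.normal(0.8, 0.05))
        c_prime = 0.0 if k % 2 == 0 else abs(rng.normal(0.3, 0.05))
        ct = cell_types[k % len(cell_types)]
        cond = condition_label(ct, "resting")
        trans_records.append({"snp": snp, "cis_gene": mediator,
                              "trans_gene": trans_gene, "a": a, "b": b,
                              "c_prime": c_prime, "cell_type": ct,
                              "condition": cond})
        cis = pd.concat([cis, pd.DataFrame([{
            "gene": mediator, "snp": snp, "cell_type": ct,
            "beta_resting": a, "beta_stimulated": a}])], ignore_index=True)
    trans = pd.DataFrame(trans_records,
                         columns=["snp", "cis_gene", "trans_gene", "a", "b",
                                  "c_prime", "cell_type", "condition"])

    # --- MR-causal genes: several causal cis SNPs in distinct LD blocks ---
    causal_records = []
    for k in range(cfg.n_causal_genes):
        if not pool:
            break
        gene = pool.pop(0)
        window = cis_snps_of(gene)
        chosen: list[int] = []
        for j in rng.permutation(window):
            if all(block_of[j] != block_of[c] for c in chosen):
                chosen.append(int(j))
            if len(chosen) >= cfg.ivs_per_causal_gene:
                break
        ct = cell_types[k % len(cell_types)]
        for j in chosen:
            beta = rng.choice([-1.0, 1.0]) * abs(
                rng.normal(cfg.causal_gene_eqtl_beta, 0.05))
            cis = pd.concat([cis, pd.DataFrame([{
                "gene": gene, "snp": snp_ids[j], "cell_type": ct,
                "beta_resting": beta, "beta_stimulated": beta}])],
                ignore_index=True)
        causal_records.append({"gene": gene, "disease": "disease1",
                               "effect": 0.3})
    causal_genes = pd.DataFrame(causal_records,
                                columns=["gene", "disease", "effect"])

    # --- GWAS loci sharing / not sharing causal variants with eQTLs -------
    loci = []
    eqtl_rows = cis.drop_duplicates("gene").reset_index(drop=True)
    take = rng.permutation(len(eqtl_rows))
    li = 0
    for shared in ([True] * cfg.n_gwas_loci_shared
                   + [False] * cfg.n_gwas_loci_distinct):
        while li < len(take):
            row = eqtl_rows.iloc[take[li]]
            li += 1
            window = cis_snps_of(row["gene"])
            eqtl_j = int(np.flatnonzero(snp_ids == row["snp"])[0])
            if shared:
                causal = eqtl_j
            else:
                far = [int(j) for j in window
                       if block_of[j] != block_of[eqtl_j]]
                if not far:
                    continue
                causal = int(rng.choice(far))
            loci.append({"locus": f"locus{len(loci)+1}",
                         "causal_snp": snp_ids[causal],
                         "eqtl_gene": row["gene"],
                         "eqtl_snp": row["snp"],
                         "shared_with_eqtl": shared})
            break
    gwas_loci = pd.DataFrame(loci, columns=["locus", "causal_snp",
                                            "eqtl_gene", "eqtl_snp",
                                            "shared_with_eqtl"])

    truth = TruthTable(cis=cis, trans=trans, gwas_loci=gwas_loci,
                       causal_genes=causal_genes)
    truth.validate(panel, gene_idx)
    return truth


def _gene_table(panel: GenotypePanel, cfg: SimConfig) -> pd.DataFrame:
    """Lay genes out at regular TSS spacing over the panel's chromosomes."""
    if panel.n_snps == 0:
        return pd.DataFrame(columns=["chrom", "tss"])
    chroms = panel.snps["chrom"].unique()
    span = panel.snps.groupby("chrom")["pos"].max()
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    rows = []
    g = 0
    for chrom in chroms:
        step = max(int(span[chrom] // (per_chrom + 1)), 1)
        for k in range(per_chrom):
            if g >= cfg.n_genes:
                break
            rows.append({"gene": f"gene{g:04d}", "chrom": chrom,
                         "tss": (k + 1) * step})
            g += 1
    return pd.DataFrame(rows).set_index("gene")


def gene_annotation(panel: GenotypePanel, cfg: SimConfig) -> pd.DataFrame:
    return _gene_table(panel, cfg)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(panel: GenotypePanel, truth: TruthTable,
                        cfg: SimConfig,
                        genes: pd.DataFrame | None = None) -> ExpressionStudy:
    """Generate paired-condition expression with the planted effects.

    Per sample i of gene g:
    ``y = condition effect + covariate effects + genotype effect
    + individual random intercept + N(0, noise_sd)``.
    Genotype effects are condition-specific per the truth table (resting
    vs stimulated slope within the effect's cell type). Samples of the
    same individual share the individual id across conditions; a core
    subset of individuals is retained in every condition and the rest are
    dropped at random per condition to emulate unequal post-QC sizes.
    """
    rng = cfg.rng("expression")
    genes = _gene_table(panel, cfg) if genes is None else genes
    truth.validate(panel, genes.index)

    inds = panel.individuals.to_numpy()
    n = len(inds)
    n_core = int(round(cfg.core_fraction * n))
    core = rng.choice(inds, size=min(n_core, n), replace=False)
    rest = np.array([i for i in inds if i not in set(core)])

    n_genes = genes.shape[0]
    gene_ids = genes.index

    # individual-level pieces shared across conditions
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 3))
    u_ind = rng.normal(0.0, cfg.individual_re_sd, size=(n, n_genes))
    ind_pos = {ind: i for i, ind in enumerate(inds)}

    # gene-level effect sizes for covariates and condition
    sex_eff = rng.normal(0.0, cfg.covariate_effect_sd, size=n_genes)
    pc_eff = rng.normal(0.0, cfg.covariate_effect_sd, size=(3, n_genes))
    factor_load = rng.normal(0.0, cfg.covariate_effect_sd, size=(10, n_genes))
    cond_eff = rng.normal(0.0, cfg.condition_effect_sd,
                          size=(len(cfg.conditions), n_genes))

    gpos = {g: k for k, g in enumerate(gene_ids)}
    dos = panel.dosages

    expression: dict[str, pd.DataFrame] = {}
    sheets = []
    cov_cols = ([f"x{i}" for i in range(1, 15)])
    for ci, ((cell_type, treatment), frac) in enumerate(
            zip(cfg.conditions, cfg.retention)):
        cond = condition_label(cell_type, treatment)
        n_keep = int(round(frac * n))
        extra_needed = max(n_keep - len(core), 0)
        extra = (rng.choice(rest, size=min(extra_needed, len(rest)),
                            replace=False) if extra_needed and len(rest)
                 else np.array([], dtype=rest.dtype))
        kept = np.concatenate([core, extra])
        kept = kept[np.argsort(kept)]
        ki = np.array([ind_pos[i] for i in kept])
        nk = len(kept)

        factors = rng.standard_normal((nk, 10))
        y = np.zeros((nk, n_genes))
        y += cond_eff[ci][None, :]
        y += sex[ki, None] * sex_eff[None, :]
        y += pcs[ki] @ pc_eff
        y += factors @ factor_load
        y += u_ind[ki]
        y += rng.normal(0.0, cfg.noise_sd, size=(nk, n_genes))

        stimulated = treatment != "resting"
        for _, row in truth.cis.iterrows():
            if row["cell_type"] != cell_type:
                continue
            beta = row["beta_stimulated"] if stimulated else row["beta_resting"]
            y[:, gpos[row["gene"]]] += beta * dos[row["snp"]].to_numpy()[ki]
        # trans outcomes: effect flows through the realised mediator value
        for _, row in truth.trans.iterrows():
            if row["cell_type"] != cell_type:
                continue
            med = y[:, gpos[row["cis_gene"]]]
            g = dos[row["snp"]].to_numpy()[ki]
            y[:, gpos[row["trans_gene"]]] += row["b"] * med + row["c_prime"] * g

        sample_ids = [f"{ind}_{cond}" for ind in kept]
        expression[cond] = pd.DataFrame(
            y, index=pd.Index(sample_ids, name="sample"), columns=gene_ids)
        sheet = pd.DataFrame(
            np.column_stack([sex[ki, None], pcs[ki], factors]),
            index=pd.Index(sample_ids, name="sample"), columns=cov_cols)
        sheet.insert(0, "individual", kept)
        sheet.insert(1, "condition", cond)
        sheet.insert(2, "cell_type", cell_type)
        sheet.insert(3, "treatment", treatment)
        sheets.append(sheet)

    samples = pd.concat(sheets)
    return ExpressionStudy(expression=expression, genes=genes,
                           samples=samples, covariate_columns=cov_cols)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas(panel: GenotypePanel, truth: TruthTable, n_gwas: int = 20000,
                  seed: int = 0, locus_effect: float = 0.15,
                  diseases: tuple[str, ...] = ("disease1",)) -> dict[str, pd.DataFrame]:
    """Per-disease GWAS summary statistics from an individual-level liability.

    A fresh cohort of ``n_gwas`` individuals is drawn from the panel's
    generating LD model. The liability is the sum of (i) direct effects of
    planted GWAS-locus causal SNPs and (ii) causal-gene effects transmitted
    through each gene's planted eQTL SNPs, plus standard-normal noise.
    Marginal per-SNP OLS gives beta, SE and p for every panel SNP.
    """
    if panel.sim is None:
        raise ValueError("panel lacks its generating LD model; "
                         "simulate_gwas requires a simulated panel")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(71,)))
    dos = _draw_dosages(rng, n_gwas, panel.sim["mafs"], panel.sim["blocks"],
                        panel.sim["latent_rhos"]).astype(np.float64)
    snp_ids = panel.snps.index
    jpos = {s: j for j, s in enumerate(snp_ids)}

    out: dict[str, pd.DataFrame] = {}
    for disease in diseases:
        liability = rng.standard_normal(n_gwas)
        for _, row in truth.gwas_loci.iterrows():
            liability += locus_effect * dos[:, jpos[row["causal_snp"]]]
        for _, row in truth.causal_genes.iterrows():
            if row["disease"] != disease:
                continue
            planted = truth.cis[truth.cis["gene"] == row["gene"]]
            score = np.zeros(n_gwas)
            for _, p_row in planted.iterrows():
                score += p_row["beta_resting"] * dos[:, jpos[p_row["snp"]]]
            liability += row["effect"] * score

        gc = dos - dos.mean(axis=0)
        yc = liability - liability.mean()
        sg = (gc ** 2).sum(axis=0)
        beta = gc.T @ yc / sg
        resid_ss = (yc ** 2).sum() - beta ** 2 * sg
        se = np.sqrt(resid_ss / (n_gwas - 2) / sg)
        z = beta / se
        p = 2 * stats.norm.sf(np.abs(z))
        out[disease] = pd.DataFrame({
            "snp": snp_ids, "chrom": panel.snps["chrom"].to_numpy(),
            "pos": panel.snps["pos"].to_numpy(),
            "effect_allele": panel.snps["alt"].to_numpy(),
            "other_allele": panel.snps["ref"].to_numpy(),
            "beta": beta, "se": se, "p": np.clip(p, 1e-300, 1.0),
        }).set_index("snp")
    return out


def with_flipped_alleles(gwas: pd.DataFrame, frac: float = 0.5,
                         seed: int = 0) -> pd.DataFrame:
    """Export mode that swaps effect/other alleles (and beta sign) for a
    random subset of SNPs; harmonisation must restore the original."""
    rng = np.random.default_rng(seed)
    out = gwas.copy()
    flip = rng.random(len(out)) < frac
    ea = out["effect_allele"].to_numpy().copy()
    oa = out["other_allele"].to_numpy().copy()
    out.loc[flip, "effect_allele"] = oa[flip]
    out.loc[flip, "other_allele"] = ea[flip]
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    return out


def simulate_study(cfg: SimConfig, n_gwas: int = 20000
                   ) -> tuple[GenotypePanel, ExpressionStudy, TruthTable,
                              dict[str, pd.DataFrame]]:
    """Convenience wrapper producing the full synthetic bundle."""
    panel = simulate_genotypes(cfg)
    genes = _gene_table(panel, cfg)
    truth = plant_truth(panel, cfg)
    study = simulate_expression(panel, truth, cfg, genes=genes)
    gwas = simulate_gwas(panel, truth, n_gwas=n_gwas, seed=cfg.seed)
    return panel, study, truth, gwas


def write_bundle(outdir, panel: GenotypePanel, study: ExpressionStudy,
                 truth: TruthTable, gwas: dict[str, pd.DataFrame],
                 cfg: SimConfig, vcf: bool = False) -> None:
    """Write the full synthetic bundle as plain-text files."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if vcf:
        panel.write_vcf(outdir / "genotypes.vcf")
        panel.snps.to_csv(outdir / "snps.tsv", sep="\t", index_label="snp")
    else:
        panel.write_tsv(outdir / "genotypes.tsv", outdir / "snps.tsv")
    study.write_tsv(outdir)
    study.write_gene_bed(outdir / "genes.bed")
    for disease, frame in gwas.items():
        frame.to_csv(outdir / f"gwas_{disease}.tsv", sep="\t",
                     index_label="snp")
    truth.to_json(outdir / "truth.json")
    cfg_dict = asdict(cfg)
    cfg_dict["conditions"] = [list(c) for c in cfg.conditions]
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(cfg_dict, fh, indent=1, default=float)
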