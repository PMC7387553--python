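"""Bayesian colocalisation of cis-eQTL and GWAS signals.

Per SNP, an approximate Bayes factor against the null is computed from the
estimate and its standard error with a Gaussian effect prior of variance W:
with z = beta/se, V = se^2 and r = W/(W+V),

    log ABF = 0.5 * log(1 - r) + z^2 * r / 2.

Assuming at most one causal variant per trait in the locus, the evidence
for the five hypotheses (H0 no causal variant; H1/H2 causal for one trait
only; H3 distinct causal variants; H4 one shared causal variant) is an
enumeration over single-SNP configurations weighted by priors p1, p2, p12;
everything is accumulated in log space.

Locus selection and decisions follow the conservative scheme: loci where a
cis-eSNP reaches GWAS p <= 1e-6, a 400-kb window centred on the top eSNP,
loci with fewer than 25 shared SNPs skipped, prior p12 = 1e-6, loci with
PP3+PP4 < 0.8 labelled underpowered, colocalised iff PP4/PP3 >= 5, plus a
sensitivity sweep of p12 over 1e-9..1e-5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger("stimeqtl")


@dataclass
class ColocPriors:
    """Per-SNP causal priors and ABF effect-prior variances.

    ``w1``/``w2`` default to (0.15)^2 for a quantitative trait (eQTL) and
    (0.2)^2 on the log-odds scale for a binary GWAS trait.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-6
    w1: float = 0.15 ** 2
    w2: float = 0.20 ** 2

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 cannot exceed min(p1, p2)")


@dataclass
class ColocResult:
    locus: str
    n_snps: int
    pp: np.ndarray                     # PP0..PP4
    decision: str                      # colocalised | distinct | underpowered
    sensitivity: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def log_abf(beta, se, w: float) -> np.ndarray:
    """Log approximate Bayes factor for association, per SNP."""
    se = np.asarray(se, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    v = se ** 2
    r = w / (w + v)
    z = beta / se
    return 0.5 * np.log1p(-r) + z ** 2 * r / 2.0


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, safe near equality."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(eqtl: pd.DataFrame, gwas: pd.DataFrame,
                     priors: ColocPriors | None = None,
                     locus: str = "locus") -> ColocResult:
    """Posterior probabilities PP0..PP4 for one locus.

    ``eqtl`` and ``gwas`` are aligned per-SNP frames (same index order)
    with columns beta and se, alleles already harmonised.
    """
    priors = priors or ColocPriors()
    if len(eqtl) == 0:
        raise ValueError("zero SNPs in locus")
    if not eqtl.index.equals(gwas.index):
        raise ValueError("eqtl and gwas SNP sets must be aligned")
    l1 = log_abf(eqtl["beta"].to_numpy(), eqtl["se"].to_numpy(), priors.w1)
    l2 = log_abf(gwas["beta"].to_numpy(), gwas["se"].to_numpy(), priors.w2)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(priors.p1) + lsum1
    lh[2] = np.log(priors.p2) + lsum2
    # sum over i != j of ABF1_i * ABF2_j
    cross = _logdiffexp(lsum1 + lsum2, lsum12)
    lh[3] = (np.log(priors.p1) + np.log(priors.p2) + cross
             if len(eqtl) > 1 else -np.inf)
    lh[4] = np.log(priors.p12) + lsum12
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(locus=locus, n_snps=len(eqtl), pp=pp,
                       decision=decide(pp))


def decide(pp: np.ndarray, power_min: float = 0.8,
           ratio_min: float = 5.0) -> str:
    """Decision rule: underpowered if PP3+PP4 < 0.8; colocalised if
    PP4/PP3 >= 5; otherwise distinct."""
    pp3, pp4 = float(pp[3]), float(pp[4])
    if pp3 + pp4 < power_min:
        return "underpowered"
    if pp3 == 0.0 or pp4 / pp3 >= ratio_min:
        return "colocalised"
    return "distinct"


def p12_sensitivity(eqtl: pd.DataFrame, gwas: pd.DataFrame,
                    priors: ColocPriors | None = None, locus: str = "locus",
                    grid: np.ndarray | None = None) -> pd.DataFrame:
    """Posteriors and decisions over a log-spaced p12 grid (1e-9..1e-5)."""
    priors = priors or ColocPriors()
    grid = np.logspace(-9, -5, 9) if grid is None else np.asarray(grid)
    rows = []
    for p12 in grid:
        pr = ColocPriors(p1=priors.p1, p2=priors.p2, p12=float(p12),
                         w1=priors.w1, w2=priors.w2)
        res = coloc_posteriors(eqtl, gwas, pr, locus=locus)
        rows.append({"p12": float(p12),
                     **{f"pp{i}": res.pp[i] for i in range(5)},
                     "decision": res.decision})
    table = pd.DataFrame(rows)
    table.attrs["robust"] = table["decision"].nunique() == 1
    return table


def select_coloc_loci(egenes: pd.DataFrame, assoc: pd.DataFrame,
                      gwas: pd.DataFrame, snps: pd.DataFrame,
                      gwas_p: float = 1e-6, window: int = 400_000,
                      min_snps: int = 25) -> list[dict]:
    """Candidate loci: eGenes whose significant eSNPs reach GWAS p <= 1e-6.

    Windows span the top cis-eSNP +/- window/2 (inclusive); the SNP set is
    the intersection of the eQTL scan and the GWAS summary; loci with
    fewer than ``min_snps`` shared SNPs are skipped (flagged, not
    returned).
    """
    loci = []
    half = window // 2
    for _, row in egenes[egenes["egene"]].iterrows():
        esnps = [s for s in row["esnps"] if s in gwas.index]
        if not any(gwas.loc[s, "p"] <= gwas_p for s in esnps):
            continue
        top = row["top_snp"]
        centre = snps.loc[top, "pos"]
        chrom = snps.loc[top, "chrom"]
        in_window = snps[(snps["chrom"] == chrom)
                         & (np.abs(snps["pos"] - centre) <= half)].index
        sub = assoc[(assoc["gene"] == row["gene"])
                    & assoc["snp"].isin(in_window)]
        shared = sub[sub["snp"].isin(gwas.index)]
        if len(shared) < min_snps:
            logger.info("locus at %s skipped: %d shared SNPs (<%d)",
                        top, len(shared), min_snps)
            continue
        loci.append({"locus": f"{row['gene']}@{top}", "gene": row["gene"],
                     "top_snp": top,
                     "eqtl": shared.set_index("snp")[["beta", "se", "p"]],
                     "gwas": gwas.loc[shared["snp"], ["beta", "se", "p"]]})
    return loci


def harmonise_gwas_to_eqtl(gwas: pd.DataFrame, snps: pd.DataFrame,
                           drop_ambiguous: bool = True) -> pd.DataFrame:
    """Align GWAS effect alleles to the panel's alt allele.

    Flips the GWAS beta when effect/other alleles are swapped relative to
    alt/ref; drops strand-ambiguous (A/T, C/G) SNPs and allele mismatches.
    """
    shared = gwas.index.intersection(snps.index)
    g = gwas.loc[shared].copy()
    ref = snps.loc[shared, "ref"]
    alt = snps.loc[shared, "alt"]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    ambiguous = g["effect_allele"].map(comp) == g["other_allele"]
    same = (g["effect_allele"] == alt) & (g["other_allele"] == ref)
    swapped = (g["effect_allele"] == ref) & (g["other_allele"] == alt)
    g.loc[swapped, "beta"] = -g.loc[swapped, "beta"]
    g.loc[swapped, ["effect_allele", "other_allele"]] = \
        np.column_stack([alt[swapped], ref[swapped]])
    keep = (same | swapped)
    if drop_ambiguous:
        keep &= ~ambiguous
    return g.loc[keep]


GWAS_COLUMN_SYNONYMS = {
    "snp": ["snp", "rsid", "variant_id", "id", "markername"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "effect_allele": ["effect_allele", "a1", "ea", "alt"],
    "other_allele": ["other_allele", "a2", "oa", "ref", "non_effect_allele"],
    "beta": ["beta", "effect", "b"],
    "se": ["se", "standard_error", "stderr"],
    "p": ["p", "pval", "p_value", "pvalue"],
}


def read_gwas_tsv(path, column_map: dict[str, str] | None = None
                  ) -> pd.DataFrame:
    """Read GWAS summary statistics, tolerant of common column synonyms."""
    raw = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in raw.columns}
    rename = {}
    for canon, alts in GWAS_COLUMN_SYNONYMS.items():
        src = (column_map or {}).get(canon)
        if src is None:
            src = next((lower[a] for a in alts if a in lower), None)
        if src is None:
            raise KeyError(f"no column found for '{canon}' in {path}")
        rename[src] = canon
    out = raw.rename(columns=rename)[list(GWAS_COLUMN_SYNONYMS)]
    return out.set_index("snp")
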