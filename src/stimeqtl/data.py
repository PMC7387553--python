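"""Core data containers: genotype panel and paired-condition expression study.

Positions are 1-based inclusive throughout. Dosages count copies of the
alternative allele (0-2, real-valued to allow imputed dosages).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("stimeqtl")

SNP_COLUMNS = ["chrom", "pos", "ref", "alt", "maf"]


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP from a (n x m) dosage matrix.

    Missing entries (NaN) are ignored. The alternative-allele frequency is
    folded onto [0, 0.5].
    """
    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(np.asarray(dosages, dtype=float), axis=0) / 2.0
    return np.minimum(alt_freq, 1.0 - alt_freq)


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x SNPs) plus per-SNP metadata.

    ``snps`` is indexed by SNP id with columns chrom, pos (1-based), ref,
    alt and maf; ``dosages`` shares the SNP ids as columns and individual
    ids as index.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame
    sim: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.snps.index):
            raise ValueError("dosage columns and SNP table index must match")
        if self.snps.index.has_duplicates:
            raise ValueError("SNP ids must be unique")
        if len(self.snps) and (self.snps["pos"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")

    @property
    def individuals(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_snps(self) -> int:
        return self.snps.shape[0]

    def subset(self, snp_ids) -> "GenotypePanel":
        snp_ids = pd.Index(snp_ids)
        return GenotypePanel(self.dosages.loc[:, snp_ids],
                             self.snps.loc[snp_ids], sim=self.sim)

    def refresh_maf(self) -> "GenotypePanel":
        """Recompute the maf column from the dosage matrix."""
        snps = self.snps.copy()
        snps["maf"] = compute_maf(self.dosages.to_numpy())
        return GenotypePanel(self.dosages, snps, sim=self.sim)

    def ld_r2(self, snp_a: str, snp_b: str) -> float:
        """Squared Pearson correlation between two SNPs' dosages."""
        a = self.dosages[snp_a].to_numpy(float)
        b = self.dosages[snp_b].to_numpy(float)
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    # ---- I/O -------------------------------------------------------------

    def write_tsv(self, dosage_path, snp_path) -> None:
        self.dosages.to_csv(dosage_path, sep="\t", index_label="individual")
        self.snps.to_csv(snp_path, sep="\t", index_label="snp")

    @classmethod
    def read_tsv(cls, dosage_path, snp_path) -> "GenotypePanel":
        dosages = pd.read_csv(dosage_path, sep="\t", index_col="individual")
        snps = pd.read_csv(snp_path, sep="\t", index_col="snp")
        return cls(dosages, snps[SNP_COLUMNS])

    def write_vcf(self, path) -> None:
        """Write a minimal text VCF 4.2 with GT (hard call) and DS fields."""
        inds = list(self.dosages.index.astype(str))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(inds) + "\n")
            gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
            dos = self.dosages.to_numpy(float)
            for j, (snp_id, row) in enumerate(self.snps.iterrows()):
                cells = []
                for d in dos[:, j]:
                    if np.isnan(d):
                        cells.append("./.:.")
                    else:
                        cells.append(f"{gt_codes[int(round(d))]}:{d:g}")
                fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\t"
                         f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT:DS\t"
                         + "\t".join(cells) + "\n")

    @classmethod
    def read_vcf(cls, path) -> "GenotypePanel":
        """Read a VCF into a panel via cyvcf2, preferring DS over GT."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        inds = list(vcf.samples)
        ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
        for var in vcf:
            ids.append(var.ID or f"{var.CHROM}_{var.POS}")
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0] if var.ALT else ".")
            ds = var.format("DS")
            if ds is not None:
                rows.append(np.asarray(ds, float).ravel())
            else:
                gt = np.asarray(var.gt_types, float)  # 0,1,2,3(=unknown)
                gt[gt == 2] = np.nan
                gt[gt == 3] = 2.0
                rows.append(gt)
        dosages = pd.DataFrame(np.column_stack(rows) if rows
                               else np.empty((len(inds), 0)),
                               index=pd.Index(inds, name="individual"),
                               columns=pd.Index(ids, name="snp"))
        snps = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs,
                             "alt": alts,
                             "maf": compute_maf(dosages.to_numpy())},
                            index=pd.Index(ids, name="snp"))
        return cls(dosages, snps)


@dataclass
class ExpressionStudy:
    """Per-condition expression matrices with gene annotation and samples.

    ``expression`` maps a condition label to a (samples x genes) DataFrame.
    ``genes`` is indexed by gene id with columns chrom and tss (1-based).
    ``samples`` is indexed by sample id with columns individual, condition,
    cell_type and the covariate columns (``x1`` ... ``x14`` by default).
    """

    expression: dict[str, pd.DataFrame]
    genes: pd.DataFrame
    samples: pd.DataFrame
    covariate_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.covariate_columns:
            self.covariate_columns = [c for c in self.samples.columns
                                      if c.startswith("x")]
        for cond, mat in self.expression.items():
            sheet = self.samples[self.samples["condition"] == cond]
            if not mat.index.isin(sheet.index).all():
                raise ValueError(f"samples in {cond} missing from sample sheet")

    @property
    def conditions(self) -> list[str]:
        return list(self.expression)

    def condition_samples(self, condition: str) -> pd.DataFrame:
        sheet = self.samples[self.samples["condition"] == condition]
        return sheet.loc[self.expression[condition].index]

    def covariates(self, condition: str) -> pd.DataFrame:
        """Covariate matrix aligned to the condition's expression rows."""
        return self.condition_samples(condition)[self.covariate_columns]

    def individuals(self, condition: str) -> pd.Series:
        return self.condition_samples(condition)["individual"]

    def write_tsv(self, outdir) -> None:
        outdir = Path(outdir)
        for cond, mat in self.expression.items():
            mat.to_csv(outdir / f"expression_{cond}.tsv", sep="\t",
                       index_label="sample")
        self.genes.to_csv(outdir / "genes.tsv", sep="\t", index_label="gene")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t",
                            index_label="sample")

    @classmethod
    def read_tsv(cls, outdir, conditions) -> "ExpressionStudy":
        outdir = Path(outdir)
        expression = {c: pd.read_csv(outdir / f"expression_{c}.tsv",
                                     sep="\t", index_col="sample")
                      for c in conditions}
        genes = pd.read_csv(outdir / "genes.tsv", sep="\t", index_col="gene")
        samples = pd.read_csv(outdir / "samples.tsv", sep="\t",
                              index_col="sample")
        return cls(expression, genes, samples)

    def write_gene_bed(self, path) -> None:
        """Gene annotation as BED-like TSV (0-based half-open TSS interval)."""
        bed = pd.DataFrame({"chrom": self.genes["chrom"],
                            "start": self.genes["tss"].astype(int) - 1,
                            "end": self.genes["tss"].astype(int),
                            "gene": self.genes.index})
        bed.to_csv(path, sep="\t", index=False, header=False)
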