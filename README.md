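# stimeqtl

Condition-aware eQTL analysis for paired resting/stimulated designs:
cis- and trans-eQTL mapping with hierarchical multiple-testing correction,
conditional dissection of independent signals, response-eQTL (reQTL)
detection by mixed-model interaction with a permutation null, mediation
analysis of trans effects through cis eGenes, Bayesian colocalisation with
disease GWAS, two-sample Mendelian randomisation, and π1 replication-rate
estimation — plus a synthetic-data generator that emulates the paired
immune-stimulation study design so the whole stack is testable without any
external download.

## Who this is for

Statistical geneticists analysing expression data measured on the same
individuals under several experimental conditions (e.g. resting vs
LPS-stimulated myeloid cells, resting vs PHA-stimulated T cells), who want
the full inference chain — from genotype/expression QC to causal claims
about disease — as one reproducible, seeded pipeline.

## The models

**Cis/trans scan.** For each gene *g* and SNP *s*, OLS of (rank-normalised)
expression on allele dosage with fixed covariates (sex, 3 genotype PCs,
10 latent expression factors): cis pairs satisfy |pos − TSS| ≤ 1 Mb,
trans pairs lie on different chromosomes. Multiple testing is hierarchical:
per-gene minima are locally adjusted by the effective number of independent
cis SNPs *M*<sub>eff</sub> (eigenvalues of the dosage correlation matrix,
99% variance, chunks of 200), Benjamini–Hochberg across genes at 5% FDR,
and the global cutoff *p*\* maps back to a per-gene nominal threshold
*p*\*/*M*<sub>eff</sub> used for eSNP calls and conditional analysis.

**Response eQTLs.** For the top eSNP of each eGene, the linear mixed model

```
y ~ x + c + x·c + x¹..x¹⁴ + x¹·c..x¹⁴·c + (1 | individual)
```

with condition *c* (resting 0, stimulated 1) is fit by profiled REML; the
x·c Wald statistic is referred to a permutation null in which each
individual's condition labels are swapped at random, giving
*p* = (*s*+1)/(*n*+1), then BH at 5% FDR.

**Mediation.** For a trans-eSNP that is also a cis-eSNP: *a* from
mediator ~ snp + covariates, *b* and *c′* from
outcome ~ snp + mediator + covariates; indirect effect *a·b*, total
*a·b + c′*, H₀: *ab* = 0 tested by bootstrap over individuals.

**Colocalisation.** Wakefield approximate Bayes factors per SNP and trait,
single-causal-variant enumeration of H₀–H₄ with priors
p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁶; loci pass when PP₃+PP₄ ≥ 0.8 and
PP₄/PP₃ ≥ 5, with a p₁₂ sensitivity sweep over 10⁻⁹…10⁻⁵.

**Mendelian randomisation.** LD-pruned (r² < 0.1) cis-eSNPs as
instruments (≥ 3), four estimators (IVW, weighted median, weighted mode,
MR-Egger); verdicts require ≥ 3 of 4 methods at p ≤ 0.05 and no
significant Egger intercept.

## Worked example

```python
import stimeqtl as sq

cfg = sq.SimConfig(n_individuals=120, n_genes=60, n_snps=600,
                   n_cis_eqtls=12, n_reqtls=4, n_signflip_reqtls=1,
                   seed=7)
panel, study, truth, gwas = sq.simulate_study(cfg, n_gwas=5000)

# rank-normalise expression and map cis-eQTLs in resting T cells
int_expr = {c: sq.int_transform_matrix(m) for c, m in study.expression.items()}
astudy = sq.ExpressionStudy(int_expr, study.genes, study.samples)
ctx, assoc, egenes = sq.map_condition(astudy, panel, "t_resting")
hits = egenes[egenes["egene"]]
print(f"tested {assoc['gene'].nunique()} genes, "
      f"{len(hits)} eGenes at 5% FDR")
print(hits[["gene", "top_snp", "beta", "p_local", "q_global"]]
      .head(3).to_string(index=False))

# response eQTLs in T cells
res = sq.run_reqtl(study, panel, "t",
                   {"t_resting": egenes,
                    "t_pha": sq.map_condition(astudy, panel, "t_pha")[2]},
                   expression_override=int_expr, n_perm=200, seed=7)
print(f"reQTL tests: {len(res)}, significant at 5% FDR: "
      f"{int(res['significant'].sum())}")
```

prints

```
tested 60 genes, 6 eGenes at 5% FDR
    gene  top_snp      beta  p_local  q_global
gene0004 snp00085  0.657081 0.000015  0.000391
gene0013 snp00126 -0.651878 0.000026  0.000391
gene0024 snp00245  0.754252 0.000796  0.007963
reQTL tests: 7, significant at 5% FDR: 1
```

Six of the twelve planted cis effects reach genome-wide 5% FDR in this
single condition at n = 112 (the rest were planted in myeloid cells or
fall below power at this sample size); betas are in s.d. of expression
per alternative allele. One of the planted T-cell response effects is
recovered as a significant reQTL from 200 permutations.

The same stages are available from the shell:

```bash
stimeqtl run-all --out run1 --seed 7
stimeqtl simulate --out sim1 --seed 7 --vcf
stimeqtl validate-io sim1/genotypes.vcf sim1/genes.bed
```

`run-all` writes per-stage TSVs (eGene tables, reQTL results, trans hits,
mediation, colocalisation, MR, π1) plus a `manifest.json` whose hashes
reproduce exactly under the same seed.

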