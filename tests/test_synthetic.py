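"""Generator behaviour: dosage ranges, LD control, planted-effect
round-trips, GWAS calibration and determinism."""

import numpy as np
import pandas as pd
import pytest

import stimeqtl as sq
from stimeqtl.synthetic import _gene_table


def adjacent_corrs(panel):
    d = panel.dosages.to_numpy()
    return [np.corrcoef(d[:, a], d[:, b])[0, 1]
            for idx in panel.sim["blocks"]
            for a, b in zip(idx[:-1], idx[1:])]


class TestGenotypes:
    def test_dosage_range_and_shape(self):
        cfg = sq.SimConfig(n_individuals=2, n_snps=3, n_genes=2, seed=1)
        panel = sq.simulate_genotypes(cfg)
        assert panel.dosages.shape == (2, 3)
        assert panel.dosages.to_numpy().min() >= 0
        assert panel.dosages.to_numpy().max() <= 2

    def test_empty_config_gives_empty_panel(self):
        cfg = sq.SimConfig(n_snps=0, n_genes=2, seed=1)
        panel = sq.simulate_genotypes(cfg)
        assert panel.n_snps == 0

    def test_independent_blocks_have_no_ld(self):
        cfg = sq.SimConfig(n_individuals=1000, n_snps=200, n_genes=5,
                           within_block_r=0.0, seed=2)
        panel = sq.simulate_genotypes(cfg)
        assert np.mean(np.abs(adjacent_corrs(panel))) < 0.1

    def test_adjacent_correlation_hits_target(self):
        # empirical mean over seeded replicates at a strong-LD target
        means = []
        for seed in range(5):
            cfg = sq.SimConfig(n_individuals=2000, n_snps=200, n_genes=5,
                               within_block_r=0.8, seed=seed)
            means.append(np.mean(adjacent_corrs(sq.simulate_genotypes(cfg))))
        assert 0.7 <= np.mean(means) <= 0.9

    def test_sample_maf_respects_floor(self, small_bundle):
        maf = sq.compute_maf(small_bundle["panel"].dosages.to_numpy())
        assert maf.min() >= 0.08 - 0.03  # sampling tolerance at n=120

    def test_seed_determinism(self, small_cfg):
        a = sq.simulate_genotypes(small_cfg)
        b = sq.simulate_genotypes(small_cfg)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sq.SimConfig(maf_range=(0.05, 0.5))
        with pytest.raises(ValueError):
            sq.SimConfig(n_reqtls=2, n_signflip_reqtls=3)
        with pytest.raises(ValueError):
            sq.SimConfig(within_block_r=1.0)


class TestExpression:
    def test_noiseless_additive_effect_is_exact(self):
        cfg = sq.SimConfig(n_individuals=200, n_genes=10, n_snps=100,
                           n_cis_eqtls=1, n_reqtls=0, n_signflip_reqtls=0,
                           n_trans_trios=0, n_causal_genes=0, noise_sd=0.0,
                           individual_re_sd=0.0, covariate_effect_sd=0.0,
                           condition_effect_sd=0.0, seed=5)
        panel = sq.simulate_genotypes(cfg)
        truth = sq.plant_truth(panel, cfg)
        study = sq.simulate_expression(panel, truth, cfg)
        row = truth.cis.iloc[0]
        cond = f"{row['cell_type']}_resting"
        sheet = study.condition_samples(cond)
        y = study.expression[cond][row["gene"]].to_numpy()
        g = panel.dosages.loc[sheet["individual"], row["snp"]].to_numpy()
        if 2 in g and 0 in g:
            diff = y[g == 2].mean() - y[g == 0].mean()
            assert diff == pytest.approx(2 * row["beta_resting"], abs=1e-9)

    def test_truth_round_trip_ols_at_low_noise(self):
        cfg = sq.SimConfig(n_individuals=150, n_genes=30, n_snps=300,
                           n_cis_eqtls=5, n_reqtls=0, n_signflip_reqtls=0,
                           n_trans_trios=0, n_causal_genes=0, noise_sd=1e-6,
                           individual_re_sd=0.0, covariate_effect_sd=0.0,
                           seed=6)
        panel = sq.simulate_genotypes(cfg)
        truth = sq.plant_truth(panel, cfg)
        study = sq.simulate_expression(panel, truth, cfg)
        for _, row in truth.cis.iterrows():
            cond = f"{row['cell_type']}_resting"
            sheet = study.condition_samples(cond)
            y = study.expression[cond][row["gene"]].to_numpy()
            g = panel.dosages.loc[sheet["individual"], row["snp"]].to_numpy()
            beta = np.polyfit(g, y, 1)[0]
            assert beta == pytest.approx(row["beta_resting"], abs=1e-4)

    def test_null_t_statistics_are_calibrated(self):
        from scipy import stats as st
        cfg = sq.SimConfig(n_individuals=150, n_genes=100, n_snps=100,
                           n_cis_eqtls=0, n_reqtls=0, n_signflip_reqtls=0,
                           n_trans_trios=0, n_causal_genes=0,
                           n_gwas_loci_shared=0, n_gwas_loci_distinct=0,
                           covariate_effect_sd=0.0, individual_re_sd=0.0,
                           condition_effect_sd=0.0, seed=7)
        panel = sq.simulate_genotypes(cfg)
        truth = sq.plant_truth(panel, cfg)
        study = sq.simulate_expression(panel, truth, cfg)
        cond = study.conditions[0]
        y = study.expression[cond].to_numpy()
        g = panel.dosages.loc[
            study.condition_samples(cond)["individual"]].to_numpy()
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(1000):
            gi = rng.integers(0, y.shape[1])
            sj = rng.integers(0, g.shape[1])
            r, p = st.pearsonr(y[:, gi], g[:, sj])
            ps.append(p)
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_signflip_recovered_by_per_condition_ols(self):
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            cfg = sq.SimConfig(n_individuals=120, n_genes=10, n_snps=60,
                               n_cis_eqtls=1, n_reqtls=1,
                               n_signflip_reqtls=1, n_trans_trios=0,
                               n_causal_genes=0, retention=(1, 1, 1, 1),
                               effect_size_sd=0.5, noise_sd=1.0, seed=seed)
            panel = sq.simulate_genotypes(cfg)
            truth = sq.plant_truth(panel, cfg)
            study = sq.simulate_expression(panel, truth, cfg)
            row = truth.cis.iloc[0]
            ct = row["cell_type"]
            stim = {"myeloid": "lps", "t": "pha"}[ct]
            slopes = []
            for tr in ("resting", stim):
                cond = f"{ct}_{tr}"
                sheet = study.condition_samples(cond)
                y = study.expression[cond][row["gene"]].to_numpy()
                g = panel.dosages.loc[sheet["individual"],
                                      row["snp"]].to_numpy()
                slopes.append(np.polyfit(g, y, 1)[0])
            if slopes[0] * slopes[1] < 0:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_sample_counts_follow_retention(self, small_bundle):
        cfg, study = small_bundle["cfg"], small_bundle["study"]
        for (ct, tr), frac in zip(cfg.conditions, cfg.retention):
            cond = f"{ct}_{tr}"
            assert study.expression[cond].shape[0] == round(
                frac * cfg.n_individuals)

    def test_paired_samples_share_individuals(self, small_bundle):
        study = small_bundle["study"]
        inds = [set(study.individuals(c)) for c in study.conditions]
        core = set.intersection(*inds)
        cfg = small_bundle["cfg"]
        assert len(core) >= round(cfg.core_fraction * cfg.n_individuals)

    def test_unknown_truth_identifier_fails(self, small_bundle):
        cfg, panel = small_bundle["cfg"], small_bundle["panel"]
        truth = small_bundle["truth"]
        bad = sq.TruthTable(
            cis=pd.concat([truth.cis, pd.DataFrame([{
                "gene": "nonexistent", "snp": truth.cis.iloc[0]["snp"],
                "cell_type": "t", "beta_resting": 1.0,
                "beta_stimulated": 1.0}])], ignore_index=True),
            trans=truth.trans, gwas_loci=truth.gwas_loci,
            causal_genes=truth.causal_genes)
        with pytest.raises(KeyError, match="nonexistent"):
            sq.simulate_expression(panel, bad, cfg)


class TestGwas:
    def test_null_gwas_lambda_near_one(self):
        from scipy import stats as st
        lams = []
        for seed in range(5):
            cfg = sq.SimConfig(n_individuals=50, n_genes=20, n_snps=200,
                               n_cis_eqtls=0, n_reqtls=0,
                               n_signflip_reqtls=0, n_trans_trios=0,
                               n_causal_genes=0, n_gwas_loci_shared=0,
                               n_gwas_loci_distinct=0, seed=seed)
            panel = sq.simulate_genotypes(cfg)
            truth = sq.plant_truth(panel, cfg)
            gwas = sq.simulate_gwas(panel, truth, n_gwas=3000, seed=seed)
            chi2 = st.chi2.isf(gwas["disease1"]["p"], df=1)
            lams.append(np.median(chi2) / st.chi2.ppf(0.5, df=1))
        assert 0.9 <= np.mean(lams) <= 1.1

    def test_shared_locus_top_snp_is_eqtl_snp(self, small_bundle):
        hits, total = 0, 0
        for seed in range(10):
            cfg = sq.SimConfig(n_individuals=100, n_genes=20, n_snps=200,
                               n_cis_eqtls=2, n_reqtls=0, n_signflip_reqtls=0,
                               n_trans_trios=0, n_causal_genes=0, n_gwas_loci_shared=1,
                               n_gwas_loci_distinct=0, seed=seed + 100)
            panel = sq.simulate_genotypes(cfg)
            truth = sq.plant_truth(panel, cfg)
            if truth.gwas_loci.empty:
                continue
            gwas = sq.simulate_gwas(panel, truth, n_gwas=20000, seed=seed)
            locus = truth.gwas_loci.iloc[0]
            centre = panel.snps.loc[locus["causal_snp"], "pos"]
            chrom = panel.snps.loc[locus["causal_snp"], "chrom"]
            window = panel.snps[(panel.snps["chrom"] == chrom) &
                                (abs(panel.snps["pos"] - centre) <= 200_000)]
            top = gwas["disease1"].loc[window.index, "p"].idxmin()
            total += 1
            hits += top == locus["causal_snp"]
        assert total and hits / total >= 0.8

    def test_allele_flip_is_involution_under_harmonisation(self, small_bundle):
        gwas = small_bundle["gwas"]["disease1"]
        flipped = sq.with_flipped_alleles(gwas, frac=0.5, seed=3)
        restored = sq.harmonise_gwas_to_eqtl(flipped,
                                             small_bundle["panel"].snps)
        common = restored.index
        assert np.allclose(restored["beta"], gwas.loc[common, "beta"])
        assert (restored["effect_allele"]
                == gwas.loc[common, "effect_allele"]).all()

    def test_gene_table_positions_positive(self, small_bundle):
        genes = _gene_table(small_bundle["panel"], small_bundle["cfg"])
        assert (genes["tss"] > 0).all()
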