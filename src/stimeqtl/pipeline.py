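"""Pipeline orchestration: simulate -> preprocess -> cis -> signals ->
reqtl -> trans -> mediate -> coloc -> mr -> pi1, with a run manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records the config snapshot, seeds, output hashes and per-stage row
counts so that a rerun with the same manifest reproduces identical
outputs. Any stage can be skipped; downstream stages that need its
outputs refuse to run.

Every threshold of the analysis is surfaced as a named config key with
its conventional default (cis window 1 Mb, FDR 5%, reQTL LD rule r^2 0.8,
MR pruning r^2 0.1, GWAS locus p 1e-6, coloc p12 1e-6, 1000 permutations,
10000 bootstrap draws, >= 3 instruments, analysis MAF floor 0.10).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cis as cis_mod
from . import coloc as coloc_mod
from . import mediation as med_mod
from . import mr as mr_mod
from . import replication as rep_mod
from . import reqtl as reqtl_mod
from . import signals as sig_mod
from . import trans as trans_mod
from .data import ExpressionStudy
from .preprocess import analysis_maf_filter, genotype_qc, int_transform_matrix
from .synthetic import SimConfig, simulate_study, write_bundle

logger = logging.getLogger("stimeqtl")

ALL_STAGES = ["simulate", "preprocess", "cis", "signals", "reqtl", "trans",
              "mediate", "coloc", "mr", "pi1"]

DEFAULT_CONFIG = {
    "stages": ALL_STAGES,
    "simulate": {},                      # SimConfig overrides
    "n_gwas": 20000,
    "maf_min": 0.10,
    "cis_window_bp": 1_000_000,
    "fdr": 0.05,
    "reqtl_r2": 0.8,
    "reqtl_n_perm": 1000,
    "mediation_n_boot": 10000,
    "mr_prune_r2": 0.1,
    "mr_min_ivs": 3,
    "gwas_locus_p": 1e-6,
    "coloc_window_bp": 400_000,
    "coloc_min_snps": 25,
    "coloc_p12": 1e-6,
    "trans_store_p": 1e-5,
}


class PipelineError(RuntimeError):
    pass


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_all(config: dict | None = None, outdir="stimeqtl_run",
            seed: int = 0) -> dict:
    """Execute the configured stages in order; returns the manifest.

    Writes per-stage TSV/JSON outputs under ``outdir`` and a
    ``manifest.json`` with config snapshot, seeds, hashes and row counts.
    """
    config = {**DEFAULT_CONFIG, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config["stages"])
    state: dict = {}
    manifest = {"config": {k: v for k, v in config.items()},
                "seed": seed, "stages_run": [], "row_counts": {}}

    def need(key: str, stage: str):
        if key not in state:
            raise PipelineError(
                f"stage '{stage}' requires outputs of a skipped stage "
                f"(missing '{key}')")

    # ---- simulate --------------------------------------------------------
    if "simulate" in stages:
        sim_cfg = SimConfig(**{**config["simulate"], "seed": seed})
        panel, study, truth, gwas = simulate_study(sim_cfg,
                                                   n_gwas=config["n_gwas"])
        write_bundle(outdir, panel, study, truth, gwas, sim_cfg)
        state.update(panel=panel, study=study, truth=truth, gwas=gwas)
        manifest["stages_run"].append("simulate")
        manifest["row_counts"]["simulate"] = {
            "snps": panel.n_snps, "genes": study.genes.shape[0],
            "samples": study.samples.shape[0]}

    # ---- preprocess ------------------------------------------------------
    if "preprocess" in stages:
        need("panel", "preprocess")
        panel = analysis_maf_filter(genotype_qc(state["panel"]),
                                    min_maf=config["maf_min"])
        study = state["study"]
        int_expr = {c: int_transform_matrix(m)
                    for c, m in study.expression.items()}
        analysis_study = ExpressionStudy(
            expression=int_expr, genes=study.genes, samples=study.samples,
            covariate_columns=study.covariate_columns)
        state.update(panel=panel, analysis_study=analysis_study)
        manifest["stages_run"].append("preprocess")
        manifest["row_counts"]["preprocess"] = {"snps_after_qc": panel.n_snps}

    # ---- cis -------------------------------------------------------------
    if "cis" in stages:
        need("analysis_study", "cis")
        contexts, assocs, egenes = {}, {}, {}
        for cond in state["analysis_study"].conditions:
            ctx, assoc, eg = cis_mod.map_condition(
                state["analysis_study"], state["panel"], cond,
                fdr=config["fdr"], window_bp=config["cis_window_bp"])
            contexts[cond], assocs[cond], egenes[cond] = ctx, assoc, eg
            eg.drop(columns="esnps").to_csv(
                outdir / f"egenes_{cond}.tsv", sep="\t", index=False)
            assoc.to_csv(outdir / f"cis_{cond}.tsv", sep="\t", index=False)
        state.update(contexts=contexts, cis_assoc=assocs, egenes=egenes)
        manifest["stages_run"].append("cis")
        manifest["row_counts"]["cis"] = {
            c: int(e["egene"].sum()) for c, e in egenes.items()}

    # ---- signals ---------------------------------------------------------
    if "signals" in stages:
        need("egenes", "signals")
        sig_rows = []
        for cond, eg in state["egenes"].items():
            ctx = state["contexts"][cond]
            for _, row in eg[eg["egene"]].iterrows():
                ss = sig_mod.dissect_gene(
                    ctx, row["gene"], row["top_snp"],
                    row["nominal_threshold"],
                    window_bp=config["cis_window_bp"])
                for _, srow in ss.stats.iterrows():
                    sig_rows.append({"gene": ss.gene, "condition": cond,
                                     **srow.to_dict()})
        signal_table = pd.DataFrame(sig_rows)
        cross = sig_mod.classify_condition_pairs(
            state["contexts"], state["egenes"],
            window_bp=config["cis_window_bp"])
        signal_table.to_csv(outdir / "signals.tsv", sep="\t", index=False)
        cross.to_csv(outdir / "cross_condition.tsv", sep="\t", index=False)
        state.update(signals=signal_table, cross_condition=cross)
        manifest["stages_run"].append("signals")
        manifest["row_counts"]["signals"] = {"signals": len(signal_table),
                                             "cross_pairs": len(cross)}

    # ---- reqtl -----------------------------------------------------------
    if "reqtl" in stages:
        need("egenes", "reqtl")
        study = state["study"]
        reqtl_tables = {}
        for cell_type in study.samples["cell_type"].unique():
            res = reqtl_mod.run_reqtl(
                study, state["panel"], cell_type, state["egenes"],
                expression_override=state["analysis_study"].expression,
                n_perm=config["reqtl_n_perm"], seed=seed,
                alpha=config["fdr"], r2_thresh=config["reqtl_r2"])
            reqtl_tables[cell_type] = res
            res.to_csv(outdir / f"reqtl_{cell_type}.tsv", sep="\t",
                       index=False)
        state["reqtl"] = reqtl_tables
        manifest["stages_run"].append("reqtl")
        manifest["row_counts"]["reqtl"] = {
            ct: int(r["significant"].sum()) if len(r) else 0
            for ct, r in reqtl_tables.items()}

    # ---- trans -----------------------------------------------------------
    if "trans" in stages:
        need("contexts", "trans")
        trans_tables, trios = {}, []
        n_genes = state["analysis_study"].genes.shape[0]
        for cond, ctx in state["contexts"].items():
            scan = trans_mod.trans_scan(ctx, store_p=config["trans_store_p"])
            flagged = trans_mod.trans_multiple_testing(
                scan, n_genes=n_genes, fdr=config["fdr"])
            trans_tables[cond] = flagged
            flagged.to_csv(outdir / f"trans_{cond}.tsv", sep="\t",
                           index=False)
            hits = flagged[flagged["genomewide_fdr_sig"]]
            linked = trans_mod.link_trans_to_cis(
                hits, state["egenes"][cond], panel=state["panel"])
            for _, row in linked.iterrows():
                trios.append({**row.to_dict(), "condition": cond})
        state.update(trans=trans_tables, trios=pd.DataFrame(trios))
        manifest["stages_run"].append("trans")
        manifest["row_counts"]["trans"] = {
            c: int(t["genomewide_fdr_sig"].sum()) if len(t) else 0
            for c, t in trans_tables.items()}

    # ---- mediate ---------------------------------------------------------
    if "mediate" in stages:
        need("trios", "mediate")
        trios = []
        for _, row in state["trios"].iterrows():
            trios.append(med_mod.build_trio(
                state["study"], state["panel"], row["cis_snp"],
                row["cis_gene"], row["trans_gene"], row["condition"],
                expression=state["analysis_study"].expression[row["condition"]]))
        med = med_mod.mediate_trios(trios, n_boot=config["mediation_n_boot"],
                                    seed=seed)
        med.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
        state["mediation"] = med
        manifest["stages_run"].append("mediate")
        manifest["row_counts"]["mediate"] = {"trios": len(med)}

    # ---- coloc -----------------------------------------------------------
    if "coloc" in stages:
        need("egenes", "coloc")
        panel = state["panel"]
        coloc_rows = []
        priors = coloc_mod.ColocPriors(p12=config["coloc_p12"])
        for disease, gw in state["gwas"].items():
            gw_h = coloc_mod.harmonise_gwas_to_eqtl(gw, panel.snps)
            for cond in state["egenes"]:
                loci = coloc_mod.select_coloc_loci(
                    state["egenes"][cond], state["cis_assoc"][cond], gw_h,
                    panel.snps, gwas_p=config["gwas_locus_p"],
                    window=config["coloc_window_bp"],
                    min_snps=config["coloc_min_snps"])
                for locus in loci:
                    res = coloc_mod.coloc_posteriors(
                        locus["eqtl"], locus["gwas"], priors,
                        locus=locus["locus"])
                    sens = coloc_mod.p12_sensitivity(
                        locus["eqtl"], locus["gwas"], priors,
                        locus=locus["locus"])
                    coloc_rows.append({
                        "locus": res.locus, "condition": cond,
                        "disease": disease, "gene": locus["gene"],
                        "n_snps": res.n_snps,
                        **{f"pp{i}": res.pp[i] for i in range(5)},
                        "decision": res.decision,
                        "robust": bool(sens.attrs["robust"])})
        coloc_table = pd.DataFrame(coloc_rows)
        coloc_table.to_csv(outdir / "coloc.tsv", sep="\t", index=False)
        state["coloc"] = coloc_table
        manifest["stages_run"].append("coloc")
        manifest["row_counts"]["coloc"] = {
            "loci": len(coloc_table),
            "colocalised": int((coloc_table["decision"] == "colocalised").sum())
            if len(coloc_table) else 0}

    # ---- mr --------------------------------------------------------------
    if "mr" in stages:
        need("egenes", "mr")
        panel = state["panel"]
        mr_rows = []
        for disease, gw in state["gwas"].items():
            for cond in state["egenes"]:
                eg = state["egenes"][cond]
                assoc = state["cis_assoc"][cond]
                for _, row in eg[eg["egene"]].iterrows():
                    esnps = row["esnps"]
                    if len(esnps) < config["mr_min_ivs"]:
                        continue
                    stats_e = assoc[(assoc["gene"] == row["gene"])
                                    & assoc["snp"].isin(esnps)].set_index("snp")
                    eqtl = pd.DataFrame({
                        "beta": stats_e["beta"], "se": stats_e["se"],
                        "p": stats_e["p"],
                        "effect_allele": panel.snps.loc[stats_e.index, "alt"],
                        "other_allele": panel.snps.loc[stats_e.index, "ref"]})
                    gwas_mr = gw.copy()
                    res = mr_mod.run_mr(row["gene"], disease, eqtl, gwas_mr,
                                        panel, r2=config["mr_prune_r2"],
                                        min_ivs=config["mr_min_ivs"],
                                        seed=seed)
                    if res is None:
                        continue
                    for _, mrow in res["methods"].iterrows():
                        mr_rows.append({
                            "gene": row["gene"], "condition": cond,
                            "disease": disease, "n_ivs": res["n_ivs"],
                            "method": mrow["method"],
                            "estimate": mrow["estimate"], "se": mrow["se"],
                            "p": mrow["p"], "verdict": res["verdict"],
                            "egger_intercept_p": res["egger_intercept_p"]})
        mr_table = pd.DataFrame(mr_rows)
        if len(mr_table):
            # a gene tested in several conditions keeps the one with the
            # most instruments (reporting rule)
            best = (mr_table.groupby(["gene", "disease", "condition"])
                    ["n_ivs"].first().reset_index()
                    .sort_values(["gene", "disease", "n_ivs", "condition"],
                                 ascending=[True, True, False, True])
                    .drop_duplicates(["gene", "disease"]))
            keep_key = set(map(tuple, best[["gene", "disease",
                                            "condition"]].to_numpy()))
            mr_table["reported"] = [
                (g, d, c) in keep_key for g, d, c in
                zip(mr_table["gene"], mr_table["disease"],
                    mr_table["condition"])]
        mr_table.to_csv(outdir / "mr.tsv", sep="\t", index=False)
        state["mr"] = mr_table
        manifest["stages_run"].append("mr")
        manifest["row_counts"]["mr"] = {"tests": len(mr_table)}

    # ---- pi1 -------------------------------------------------------------
    if "pi1" in stages:
        need("cis_assoc", "pi1")
        pi1_rows = []
        conds = list(state["cis_assoc"])
        for ca in conds:
            for cb in conds:
                if ca == cb:
                    continue
                eg = state["egenes"][ca]
                disc = []
                for _, row in eg[eg["egene"]].iterrows():
                    for snp in row["esnps"]:
                        disc.append({"gene": row["gene"], "snp": snp})
                if len(disc) < 10:
                    continue
                try:
                    est = rep_mod.replication_rate(
                        pd.DataFrame(disc), state["cis_assoc"][cb])
                except ValueError:
                    continue
                pi1_rows.append({"discovery": ca, "replication": cb,
                                 "n_pairs": est.n_pairs, "pi1": est.pi1,
                                 "note": est.note})
        pi1_table = pd.DataFrame(pi1_rows)
        pi1_table.to_csv(outdir / "pi1.tsv", sep="\t", index=False)
        state["pi1"] = pi1_table
        manifest["stages_run"].append("pi1")
        manifest["row_counts"]["pi1"] = {"pairs": len(pi1_table)}

    manifest["output_hashes"] = {
        f.name: _hash_file(f) for f in sorted(outdir.glob("*.tsv"))}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    state["manifest"] = manifest
    return state


# ---------------------------------------------------------------------------
# I/O validation
# ---------------------------------------------------------------------------

def validate_io(files: list) -> dict:
    """Lightweight conformance checks for VCF/TSV/BED/JSON inputs.

    Returns a report {path: [messages]}; an empty list means clean.
    Positions are checked against the 1-based convention (a BED-like gene
    annotation whose TSS arithmetic goes negative is flagged as likely
    0/1-based confusion).
    """
    report: dict[str, list[str]] = {}
    for path in map(Path, files):
        msgs: list[str] = []
        if not path.exists():
            report[str(path)] = ["file not found"]
            continue
        suffix = path.suffix.lower()
        lines = path.read_text().splitlines()
        if suffix == ".vcf":
            n_fields = None
            saw_header = False
            for i, line in enumerate(lines, start=1):
                if line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    saw_header = True
                    n_fields = len(line.split("\t"))
                    continue
                fields = line.split("\t")
                if n_fields is not None and len(fields) != n_fields:
                    msgs.append(f"line {i}: {len(fields)} fields, "
                                f"expected {n_fields}")
                elif len(fields) >= 2:
                    try:
                        if int(fields[1]) <= 0:
                            msgs.append(f"line {i}: non-positive position")
                    except ValueError:
                        msgs.append(f"line {i}: malformed position")
            if not saw_header:
                msgs.append("missing #CHROM header line")
        elif suffix == ".bed":
            for i, line in enumerate(lines, start=1):
                fields = line.split("\t")
                if len(fields) < 3:
                    msgs.append(f"line {i}: fewer than 3 BED fields")
                    continue
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    msgs.append(f"line {i}: non-integer interval")
                    continue
                if start < 0:
                    msgs.append(f"line {i}: negative start "
                                "(0/1-based confusion?)")
                if end <= start:
                    msgs.append(f"line {i}: empty or inverted interval")
        elif suffix == ".json":
            try:
                json.loads(path.read_text())
            except json.JSONDecodeError as err:
                msgs.append(f"invalid JSON: {err}")
        elif suffix in (".tsv", ".txt"):
            widths = {len(line.split("\t")) for line in lines if line}
            if len(widths) > 1:
                for i, line in enumerate(lines, start=1):
                    if line and len(line.split("\t")) != len(lines[0].split("\t")):
                        msgs.append(f"line {i}: ragged row")
        report[str(path)] = msgs
    return report
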