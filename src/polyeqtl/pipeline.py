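"""End-to-end orchestration: simulate -> scan -> clump -> classify ->
hotspots -> piggyback -> subgenome -> OCR -> TWAS -> TF ranking.

``run_all`` consumes a directory of standard-format inputs (genome.gff3,
genotypes.vcf, expr_20.tsv, expr_40.tsv, ocr.bed, trait.tsv,
similarity.tsv, tf_list.txt and optionally truth.json) and writes every
stage's result tables plus a machine-readable ``metrics.json``. When a
ground-truth file is present, recovery metrics against the planted
structure are added. All thresholds live in ``AnalysisParams`` with the
conventional defaults (P <= 1e-6, LD r2 0.2, 500-kb local window, 150-kb
homoeolog window, 1-Mb/100-kb hotspot scan at alpha 0.01, TWAS FDR 0.05,
top-3 TF extraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, grn_rank, hotspots as hs, ocr_enrich, piggyback, subgenome
from .formats_io import (
    Genome,
    IntervalSet,
    read_bed,
    read_expression_tsv,
    read_gff3,
    read_similarity_tsv,
    read_tf_list,
    read_trait_tsv,
    read_vcf,
    write_bed,
    write_table,
)
from .simulate import STAGE1, STAGE2, GroundTruth, SimConfig, simulate_study, write_study


@dataclass
class AnalysisParams:
    """Every analysis threshold, in one place."""

    maf_min: float = 0.05
    sig_threshold: float = 1e-6
    ld_r2_min: float = 0.2
    local_window: int = 500_000
    hgp_window: int = 150_000
    hotspot_window: int = 1_000_000
    hotspot_step: int = 100_000
    hotspot_alpha: float = 0.01
    match_window: int = 100_000
    overlap_frac: float = 0.9
    twas_fdr: float = 0.05
    propensity_fdr: float = 0.05
    top_k: int = 3
    n_perm: int = 1000
    n_pcs: int = 0
    max_grn_targets: int = 20
    grn_hyperparams: dict = field(default_factory=dict)
    seed: int = 0


def _match_planted_local(records_by_gene, rec_truth, window=100_000) -> bool:
    recs = records_by_gene.get(rec_truth.gene_id, [])
    for r in recs:
        if (r.category == "local" and r.chrom == rec_truth.chrom
                and abs(r.pos - rec_truth.pos) <= window):
            return True
    return False


def run_all(input_dir: str | Path, out_dir: str | Path,
            params: AnalysisParams | None = None) -> dict:
    """Run the full analysis over a study directory; returns the metrics."""
    params = params or AnalysisParams()
    ind, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    required = ["genome.gff3", "genotypes.vcf", "expr_20.tsv", "expr_40.tsv",
                "ocr.bed", "trait.tsv", "similarity.tsv", "tf_list.txt"]
    missing = [f for f in required if not (ind / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files in {ind}: {missing}")

    genome = read_gff3(ind / "genome.gff3")
    tf_ids = read_tf_list(ind / "tf_list.txt")
    genome = genome.with_tf_flags(tf_ids)
    gm = read_vcf(ind / "genotypes.vcf").filter_maf(params.maf_min)
    expr1 = read_expression_tsv(ind / "expr_20.tsv", stage=STAGE1)
    expr2 = read_expression_tsv(ind / "expr_40.tsv", stage=STAGE2)
    ocr = read_bed(ind / "ocr.bed", genome)
    trait = read_trait_tsv(ind / "trait.tsv")
    similarity = read_similarity_tsv(ind / "similarity.tsv")
    truth = (GroundTruth.from_json(ind / "truth.json")
             if (ind / "truth.json").exists() else None)

    metrics: dict = {}
    covariates = (assoc.genotype_pcs(gm, params.n_pcs)
                  if params.n_pcs > 0 else None)

    # ---- eQTL scan / clump / classify ------------------------------------
    recs1 = assoc.call_eqtls(gm, expr1, genome, params.sig_threshold,
                             params.ld_r2_min, params.local_window, covariates)
    recs2 = assoc.call_eqtls(gm, expr2, genome, params.sig_threshold,
                             params.ld_r2_min, params.local_window, covariates)
    assoc.stage_overlap(recs1, recs2, gm, params.match_window, params.ld_r2_min)
    write_table(assoc.eqtl_table(recs1), out / "eqtls_20.tsv")
    write_table(assoc.eqtl_table(recs2), out / "eqtls_40.tsv")
    for stage, recs in ((STAGE1, recs1), (STAGE2, recs2)):
        metrics[f"n_eqtl_{stage}"] = len(recs)
        metrics[f"n_local_{stage}"] = sum(r.category == "local" for r in recs)
        metrics[f"n_distant_{stage}"] = sum(r.category == "distant" for r in recs)
        metrics[f"n_egene_{stage}"] = len({r.gene_id for r in recs})
    both1 = sum(r.overlap_status == "both" for r in recs1)
    metrics["frac_eqtl_both_stages"] = both1 / len(recs1) if recs1 else 0.0

    # ---- hotspots ---------------------------------------------------------
    hset1, counts1, null1 = hs.detect_hotspots(
        recs1, genome, params.hotspot_window, params.hotspot_step,
        params.n_perm, params.hotspot_alpha, params.seed, STAGE1)
    hset2, _, _ = hs.detect_hotspots(
        recs2, genome, params.hotspot_window, params.hotspot_step,
        params.n_perm, params.hotspot_alpha, params.seed + 1, STAGE2)
    hs.stage_overlap_hotspots(hset1, hset2, params.overlap_frac)
    all_hs = hset1 + hset2
    write_table(hs.hotspot_table(all_hs), out / "hotspots.tsv")
    if all_hs:
        write_bed(IntervalSet(hs.hotspot_table(all_hs)[["chrom", "start", "end"]]),
                  out / "hotspots.bed")
    metrics["n_hotspots_20DAF"] = len(hset1)
    metrics["n_hotspots_40DAF"] = len(hset2)

    # ---- piggybacking (stage 1) ------------------------------------------
    rng_pb = np.random.default_rng(params.seed + 10)
    local_egenes = {r.gene_id for r in recs1 if r.category == "local"}
    census = piggyback.adjacency_census(local_egenes, genome)
    write_table(census.reset_index(), out / "census.tsv")
    observed_adjacent = int(census.loc[0])
    _, adj_p = piggyback.adjacency_permutation(
        observed_adjacent, len(local_egenes), genome, params.n_perm, rng_pb)
    metrics["n_local_egenes_20DAF"] = len(local_egenes)
    metrics["adjacent_pairs_observed"] = observed_adjacent
    metrics["adjacency_perm_p"] = adj_p
    pairs = piggyback.classify_pairs(local_egenes, genome, rng_pb)
    pairs = piggyback.pair_correlations(pairs, expr1)
    write_table(pairs, out / "pairs.tsv")
    ks_classes = piggyback.class_ks_tests(pairs)
    write_table(ks_classes, out / "class_ks.tsv")
    for _, row in ks_classes.iterrows():
        if row["class_a"] == "I" and row["class_b"] == "III":
            metrics["pcc_mean_class_I"] = row["mean_pcc_a"]
            metrics["pcc_mean_class_III"] = row["mean_pcc_b"]
            metrics["ks_p_I_vs_III"] = row["ks_p"]
    lead_by_gene: dict[str, tuple[str, int]] = {}
    for r in recs1:
        if r.category != "local":
            continue
        cur = lead_by_gene.get(r.gene_id)
        if cur is None or r.p < cur[2]:
            lead_by_gene[r.gene_id] = (r.chrom, r.pos, r.p)  # type: ignore
    lead_by_gene = {g: (c, p) for g, (c, p, _) in lead_by_gene.items()}
    strata = piggyback.chromatin_strata(
        pairs[pairs["pair_class"] == "I"], lead_by_gene, ocr)
    st_tests = piggyback.strata_tests(strata)
    write_table(st_tests, out / "strata_tests.tsv")
    for _, row in st_tests.iterrows():
        key = f"strata_t_p_{row['stratum_a']}_vs_{row['stratum_b']}"
        metrics[key] = row["t_p"]

    # ---- subgenome --------------------------------------------------------
    rbh = subgenome.rbh_pairs(similarity)
    metrics["n_rbh_pairs"] = len(rbh)
    hgp = subgenome.classify_hgps(rbh, recs1 + recs2, genome, params.hgp_window)
    hgp = subgenome.expression_propensity(hgp, expr1, params.propensity_fdr)
    hgp, fb_tests = subgenome.feedback_analysis(hgp, expr1)
    write_table(hgp, out / "hgp.tsv")
    write_table(fb_tests, out / "feedback_ks.tsv")
    metrics["n_ahgp"] = int((~hgp["symmetric"]).sum())
    metrics["n_imbalanced"] = int(hgp["imbalanced"].sum())
    for _, row in fb_tests.iterrows():
        if row["group_a"] == "Local" and row["group_b"] == "NoLocal":
            metrics["feedback_pcc_local"] = row["mean_pcc_a"]
            metrics["feedback_pcc_nolocal"] = row["mean_pcc_b"]
            metrics["feedback_ks_p"] = row["ks_p"]
    fb_genes: set[str] = set()
    for _, row in hgp[hgp["feedback_group"] == "Local"].iterrows():
        fb_genes.update((row["an_gene"], row["cn_gene"]))
    n_tf_fb, tf_p = subgenome.tf_enrichment(
        fb_genes, genome, params.n_perm,
        np.random.default_rng(params.seed + 20))
    metrics["feedback_tf_count"] = n_tf_fb
    metrics["feedback_tf_perm_p"] = tf_p

    # ---- OCR enrichment ---------------------------------------------------
    leads_all = hs.leads_frame(recs1, category=None)
    enr = ocr_enrich.ocr_permutation_test(
        leads_all, ocr, genome, params.n_perm,
        np.random.default_rng(params.seed + 30))
    metrics["ocr_leads_observed"] = enr["observed"]
    metrics["ocr_null_mean"] = enr["null_mean"]
    metrics["ocr_ci_high"] = enr["ci_high"]
    metrics["ocr_perm_p"] = enr["empirical_p"]
    write_table(
        pd.DataFrame([{k: v for k, v in enr.items() if k != "null"}]),
        out / "ocr_enrichment.tsv")
    r2_vals = np.array([r.r2 for r in recs1])
    _, flags = ocr_enrich.leads_in_ocr(leads_all, ocr)
    ks_r2 = ocr_enrich.r2_in_vs_out(r2_vals, flags)
    metrics["r2_in_vs_out_ks_p"] = ks_r2["ks_p"]

    # ---- TWAS -------------------------------------------------------------
    twas_df = assoc.twas(expr1, trait, params.twas_fdr)
    write_table(twas_df, out / "twas.tsv")
    twas_genes = set(twas_df.loc[twas_df["significant"], "gene_id"])
    metrics["n_twas_significant"] = len(twas_genes)

    # ---- hotspot-TWAS enrichment ------------------------------------------
    universe = {r.gene_id for r in recs1}
    enrich_df = hs.enrich_all_hotspots(hset1, twas_genes, universe)
    write_table(enrich_df, out / "hotspot_twas_enrichment.tsv")

    # ---- TF ranking for the strongest hotspot -----------------------------
    ranking_df = pd.DataFrame(
        columns=["tf_id", "top_k_count", "first_rank_count", "rank", "in_hotspot"])
    if hset1:
        top_hs = max(hset1, key=lambda h: (h.eqtl_count, h.chrom, h.start))
        targets = sorted(top_hs.regulated_genes)[: params.max_grn_targets]
        if targets:
            ranking_df = grn_rank.rank_hotspot_tfs(
                expr1, tf_ids, targets, top_hs, genome,
                params.grn_hyperparams or None, params.top_k, params.seed)
        metrics["grn_n_targets"] = len(targets)
    write_table(ranking_df, out / "tf_ranking.tsv")
    if len(ranking_df):
        metrics["grn_top_tf"] = str(ranking_df.iloc[0]["tf_id"])

    # ---- recovery vs ground truth -----------------------------------------
    if truth is not None:
        metrics.update(
            _recovery_metrics(truth, genome, gm, recs1, recs2, hset1, hgp,
                              twas_df, ranking_df, params))

    out_metrics = {k: (v.item() if isinstance(v, np.generic) else v)
                   for k, v in metrics.items()}
    (out / "metrics.json").write_text(
        json.dumps(out_metrics, indent=1, sort_keys=True))
    return out_metrics


def _recovery_metrics(truth, genome, gm, recs1, recs2, hset1, hgp_df,
                      twas_df, ranking_df, params) -> dict:
    m: dict = {}
    by_gene1: dict[str, list] = {}
    for r in recs1:
        by_gene1.setdefault(r.gene_id, []).append(r)

    hits = sum(
        _match_planted_local(by_gene1, rec) for rec in
        [x for x in truth.locals if STAGE1 in x.stages]
    )
    n_planted = len([x for x in truth.locals if STAGE1 in x.stages])
    m["local_detection_rate"] = hits / n_planted if n_planted else np.nan

    specific = [x for x in truth.locals if x.stages == [STAGE1]]
    if specific:
        ok = 0
        for x in specific:
            for r in by_gene1.get(x.gene_id, []):
                if (r.category == "local" and abs(r.pos - x.pos) <= 100_000
                        and r.overlap_status == "s1_only"):
                    ok += 1
                    break
        m["stage_specific_recovery"] = ok / len(specific)

    if truth.hotspots:
        hsp = truth.hotspots[0]
        found = None
        for h in hset1:
            if h.chrom == hsp.chrom and h.start <= hsp.pos < h.end:
                found = h
                break
        m["planted_hotspot_called"] = found is not None
        m["planted_hotspot_empirical_p"] = (found.empirical_p if found
                                            else np.nan)
        if found is not None:
            m["hotspot_target_recovery"] = (
                len(set(hsp.targets) & set(found.regulated_genes))
                / len(hsp.targets))
        m["n_false_hotspots_20DAF"] = sum(
            1 for h in hset1
            if not any(h.chrom == t.chrom and h.start <= t.pos < h.end
                       for t in truth.hotspots))
        if len(ranking_df):
            row = ranking_df[ranking_df["tf_id"] == hsp.regulator_gene]
            m["planted_regulator_rank"] = (int(row["rank"].iloc[0])
                                           if len(row) else -1)

    if truth.hgps:
        pair_class = {
            (row["an_gene"], row["cn_gene"]): row["reg_class"]
            for _, row in hgp_df.iterrows()
        }
        ok = sum(
            1 for h in truth.hgps
            if pair_class.get((h.an_gene, h.cn_gene)) == h.direction
        )
        m["ahgp_direction_recovery"] = ok / len(truth.hgps)

    if truth.biased_pairs:
        rows = hgp_df.set_index(["an_gene", "cn_gene"])
        sens = []
        for bp in truth.biased_pairs:
            key = (bp["an_gene"], bp["cn_gene"])
            if key in rows.index:
                r = rows.loc[key]
                sens.append(bool(r["imbalanced"]) and r["log2fc"] > 0)
        if sens:
            m["propensity_sensitivity"] = float(np.mean(sens))
        planted_pair_keys = (
            {(h.an_gene, h.cn_gene) for h in truth.hgps}
            | {(bp["an_gene"], bp["cn_gene"]) for bp in truth.biased_pairs})
        neutral = [
            bool(row["imbalanced"])
            for _, row in hgp_df.iterrows()
            if (row["an_gene"], row["cn_gene"]) not in planted_pair_keys
        ]
        if neutral:
            m["propensity_false_rate"] = float(np.mean(neutral))

    if truth.trait_causal:
        sig = set(twas_df.loc[twas_df["significant"], "gene_id"])
        causal = {t["gene_id"] for t in truth.trait_causal}
        m["twas_causal_recovery"] = len(sig & causal) / len(causal)
        m["twas_empirical_fdr"] = (len(sig - causal) / len(sig)) if sig else 0.0
    return m


def run_simulated(cfg: SimConfig, out_dir: str | Path,
                  params: AnalysisParams | None = None) -> dict:
    """Simulate a study, write its inputs, run the full analysis."""
    out = Path(out_dir)
    study = simulate_study(cfg)
    write_study(study, out / "inputs")
    return run_all(out / "inputs", out / "results", params)
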