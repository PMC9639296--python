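"""RBH pairing, regulation classes, expression propensity, feedback, TF
enrichment."""

import numpy as np
import pandas as pd
import pytest

from polyeqtl import assoc, subgenome
from polyeqtl.formats_io import ExpressionMatrix, GeneModel, Genome
from polyeqtl.simulate import STAGE1, SimConfig, simulate_study

from oracles import rbh_brute


def _sim_df(mat, an_ids, cn_ids):
    rows = [(a, c, float(mat[i, j]))
            for i, a in enumerate(an_ids) for j, c in enumerate(cn_ids)]
    return pd.DataFrame(rows, columns=["an_gene", "cn_gene", "score"])


def test_rbh_diagonal_and_broken_reciprocity():
    an, cn = ["a1", "a2", "a3"], ["c1", "c2", "c3"]
    mat = np.array([[0.9, 0.1, 0.1], [0.2, 0.8, 0.1], [0.1, 0.2, 0.95]])
    assert subgenome.rbh_pairs(_sim_df(mat, an, cn)) == [
        ("a1", "c1"), ("a2", "c2"), ("a3", "c3")]
    # a1's best is c1, but c1's best is a2 -> no pair for a1
    mat = np.array([[0.5, 0.1], [0.9, 0.8]])
    assert subgenome.rbh_pairs(_sim_df(mat, ["a1", "a2"], ["c1", "c2"])) == [
        ("a2", "c1")]


def test_rbh_tie_at_best_hit_drops_pair():
    df = pd.DataFrame({
        "an_gene": ["a1", "a1", "a2"],
        "cn_gene": ["c1", "c2", "c2"],
        "score": [0.9, 0.9, 0.3]})
    assert subgenome.rbh_pairs(df) == []


@pytest.mark.parametrize("seed", range(20))
def test_rbh_matches_brute_force(seed):
    rng = np.random.default_rng(300 + seed)
    an = [f"a{i}" for i in range(20)]
    cn = [f"c{i}" for i in range(20)]
    mat = np.round(rng.uniform(0, 1, (20, 20)), 3)
    df = _sim_df(mat, an, cn)
    got = set(subgenome.rbh_pairs(df))
    assert got == rbh_brute(df)
    # matching: injective both ways
    assert len({a for a, _ in got}) == len(got)
    assert len({c for _, c in got}) == len(got)


def test_rbh_invariant_to_row_shuffling():
    rng = np.random.default_rng(31)
    an = [f"a{i}" for i in range(10)]
    cn = [f"c{i}" for i in range(10)]
    df = _sim_df(rng.uniform(0, 1, (10, 10)), an, cn)
    shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    assert subgenome.rbh_pairs(df) == subgenome.rbh_pairs(shuffled)


# ---------------------------------------------------------------------------
# Regulation classes
# ---------------------------------------------------------------------------

def _toy_genome():
    chroms = pd.DataFrame({
        "name": ["A01", "C01"], "length": [2_000_000, 2_000_000],
        "subgenome": ["An", "Cn"]})
    genes = [
        GeneModel("a1", "A01", "+", 500_000, 502_000, 500_000),
        GeneModel("c1", "C01", "+", 500_000, 502_000, 500_000),
    ]
    return Genome(chroms, genes)


def _distant(gene, chrom, pos):
    r = assoc.EqtlRecord(gene, STAGE1, chrom, pos, 0, [0], 1e-9, 0.5, 1.0)
    r.category = "distant"
    return r


def test_regulation_class_rule_and_boundaries():
    g = _toy_genome()
    leads = subgenome.distant_leads_by_gene([])
    assert subgenome.regulation_class("a1", "c1", leads, g) == "none"
    # c1 has a distant lead 100 kb from a1's TSS -> An regulates Cn
    leads = subgenome.distant_leads_by_gene([_distant("c1", "A01", 600_000)])
    assert subgenome.regulation_class("a1", "c1", leads, g) == "An_reg_Cn"
    # boundary inclusive at exactly 150 kb, exclusive beyond
    leads = subgenome.distant_leads_by_gene([_distant("c1", "A01", 650_000)])
    assert subgenome.regulation_class("a1", "c1", leads, g) == "An_reg_Cn"
    leads = subgenome.distant_leads_by_gene([_distant("c1", "A01", 650_001)])
    assert subgenome.regulation_class("a1", "c1", leads, g) == "none"
    # both directions -> mutual (sHGP)
    leads = subgenome.distant_leads_by_gene(
        [_distant("c1", "A01", 600_000), _distant("a1", "C01", 450_000)])
    assert subgenome.regulation_class("a1", "c1", leads, g) == "mutual"


def test_regulation_class_antisymmetric():
    g = _toy_genome()
    leads = subgenome.distant_leads_by_gene([_distant("c1", "A01", 600_000)])
    assert subgenome.regulation_class("a1", "c1", leads, g) == "An_reg_Cn"
    # swapping the roles of the two genes swaps the direction label
    leads_sw = subgenome.distant_leads_by_gene([_distant("a1", "C01", 600_000)])
    g_sw = _toy_genome()
    assert subgenome.regulation_class("a1", "c1", leads_sw, g_sw) == "Cn_reg_An"


def test_planted_direction_recovery(demo_study, demo_records):
    recs1, recs2 = demo_records
    rbh = subgenome.rbh_pairs(demo_study.similarity)
    assert len(rbh) == 240  # every homoeolog slot recovered
    hgp = subgenome.classify_hgps(rbh, recs1 + recs2, demo_study.genome)
    cls = {(r["an_gene"], r["cn_gene"]): r["reg_class"]
           for _, r in hgp.iterrows()}
    ok = sum(cls.get((h.an_gene, h.cn_gene)) == h.direction
             for h in demo_study.truth.hgps)
    assert ok / len(demo_study.truth.hgps) >= 0.9


# ---------------------------------------------------------------------------
# Propensity
# ---------------------------------------------------------------------------

def _expr(an_tpm, cn_tpm):
    n = len(an_tpm)
    accs = [f"s{i}" for i in range(n)]
    vals = np.column_stack([an_tpm, cn_tpm]).astype(float)
    return ExpressionMatrix(accs, ["a1", "c1"], vals, STAGE1)


def _pair_df():
    return pd.DataFrame([{
        "an_gene": "a1", "cn_gene": "c1", "reg_class": "none",
        "symmetric": True, "local_flag_regulating": False,
        "local_flag_regulated": False}])


def test_propensity_identical_expression():
    tpm = np.random.default_rng(0).uniform(1, 50, 40)
    out = subgenome.expression_propensity(_pair_df(), _expr(tpm, tpm))
    assert out["log2fc"].iloc[0] == 0.0
    assert out["padj"].iloc[0] > 0.9
    assert not out["imbalanced"].iloc[0]


def test_propensity_exact_twofold():
    """TPM_An + 1 = 2 (TPM_Cn + 1) with constant TPM_Cn gives log2fc = 1
    exactly (and positive = An-biased by the sign convention)."""
    cn = np.full(40, 9.0)
    an = 2 * (cn + 1) - 1
    out = subgenome.expression_propensity(_pair_df(), _expr(an, cn))
    assert out["log2fc"].iloc[0] == pytest.approx(1.0)
    assert out["log2fc"].iloc[0] > 0


def test_planted_propensity_recovery(demo_study, demo_records):
    recs1, recs2 = demo_records
    rbh = subgenome.rbh_pairs(demo_study.similarity)
    hgp = subgenome.classify_hgps(rbh, recs1 + recs2, demo_study.genome)
    hgp = subgenome.expression_propensity(hgp, demo_study.expr1)
    idx = hgp.set_index(["an_gene", "cn_gene"])
    sens = []
    for b in demo_study.truth.biased_pairs:
        row = idx.loc[(b["an_gene"], b["cn_gene"])]
        sens.append(bool(row["imbalanced"]) and row["log2fc"] > 0)
    assert np.mean(sens) >= 0.9
    planted = ({(h.an_gene, h.cn_gene) for h in demo_study.truth.hgps}
               | {(b["an_gene"], b["cn_gene"])
                  for b in demo_study.truth.biased_pairs})
    neutral = [bool(r["imbalanced"]) for _, r in hgp.iterrows()
               if (r["an_gene"], r["cn_gene"]) not in planted]
    assert np.mean(neutral) <= 0.1


# ---------------------------------------------------------------------------
# Feedback
# ---------------------------------------------------------------------------

def test_cross_pcc_identity():
    tpm = np.random.default_rng(1).uniform(1, 50, 40)
    out = subgenome.cross_pcc(_pair_df(), _expr(tpm, tpm))
    assert out["cross_pcc"].iloc[0] == pytest.approx(1.0)


def test_feedback_groups_separate(demo_study, demo_records):
    """aHGPs whose regulating gene carries a local eQTL show negative
    cross-homoeolog correlation; those without do not."""
    recs1, recs2 = demo_records
    rbh = subgenome.rbh_pairs(demo_study.similarity)
    hgp = subgenome.classify_hgps(rbh, recs1 + recs2, demo_study.genome)
    df, tests = subgenome.feedback_analysis(hgp, demo_study.expr1)
    row = tests[(tests["group_a"] == "Local")
                & (tests["group_b"] == "NoLocal")].iloc[0]
    assert row["mean_pcc_a"] < row["mean_pcc_b"]
    assert row["mean_pcc_a"] < -0.3
    assert row["ks_p"] < 0.01


def test_no_feedback_no_separation():
    study = simulate_study(SimConfig(seed=22, feedback_strength=0.0))
    gm = study.genotypes.filter_maf(0.05)
    recs = assoc.call_eqtls(gm, study.expr1, study.genome)
    rbh = subgenome.rbh_pairs(study.similarity)
    hgp = subgenome.classify_hgps(rbh, recs, study.genome)
    _, tests = subgenome.feedback_analysis(hgp, study.expr1)
    row = tests[(tests["group_a"] == "Local")
                & (tests["group_b"] == "NoLocal")]
    assert len(row) == 1 and row["ks_p"].iloc[0] > 0.05


# ---------------------------------------------------------------------------
# TF enrichment
# ---------------------------------------------------------------------------

def test_tf_enrichment_degenerate(demo_study):
    genome = demo_study.genome
    no_tf = genome.with_tf_flags([])
    obs, p = subgenome.tf_enrichment({"BnaA01g0001"}, no_tf, 200, 0)
    assert obs == 0 and p == 1.0
    all_tf = genome.with_tf_flags([g.gene_id for g in genome.genes])
    obs, p = subgenome.tf_enrichment({"BnaA01g0001"}, all_tf, 200, 0)
    assert p == 1.0


def test_tf_enrichment_detects_biased_set(demo_study):
    # a 40-gene set that is half TFs (~5x the genome-wide fraction)
    genome = demo_study.genome
    tfs = genome.tf_ids()
    non_tf = [g.gene_id for g in genome.genes if not g.is_tf][:20]
    query = set(tfs[:20]) | set(non_tf)
    obs, p = subgenome.tf_enrichment(query, genome, 1000, 0)
    assert obs == 20 and p < 0.01


def test_bh_monotone_in_fdr_level(demo_study, demo_records):
    recs1, recs2 = demo_records
    rbh = subgenome.rbh_pairs(demo_study.similarity)
    hgp = subgenome.classify_hgps(rbh, recs1 + recs2, demo_study.genome)
    strict = subgenome.expression_propensity(hgp, demo_study.expr1, fdr=0.01)
    loose = subgenome.expression_propensity(hgp, demo_study.expr1, fdr=0.10)
    assert strict["imbalanced"].sum() <= loose["imbalanced"].sum()
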