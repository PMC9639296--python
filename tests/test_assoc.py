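"""Association scan, LD clumping, classification, stage overlap and TWAS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from polyeqtl import assoc
from polyeqtl.formats_io import ExpressionMatrix, GeneModel, GenotypeMatrix
from polyeqtl.simulate import STAGE1

from oracles import clump_brute, pearson_r2_brute


def _toy(dosages, expr_vals, gene="g1"):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    accs = [f"s{i}" for i in range(n)]
    snps = pd.DataFrame({
        "chrom": ["A01"] * m, "pos": np.arange(m) * 1000,
        "ref": ["A"] * m, "alt": ["G"] * m})
    gm = GenotypeMatrix(accs, snps, dosages)
    expr = ExpressionMatrix(accs, [gene], np.asarray(expr_vals, float)[:, None],
                            stage=STAGE1)
    return gm, expr


def test_scan_perfect_fit():
    """Expression exactly equal to (2^dosage - 1) gives r2 = 1 and a
    floored p-value."""
    rng = np.random.default_rng(0)
    d = rng.integers(0, 3, size=40).astype(float)
    gm, expr = _toy(d[:, None], np.power(2.0, d) - 1.0)
    out = assoc.scan_gene(gm, expr, "g1", min_shared=30)
    assert out["r2"].iloc[0] == pytest.approx(1.0)
    assert out["p"].iloc[0] <= 1e-200


def test_scan_zero_variance_expression_warns():
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, size=(40, 3)).astype(float)
    gm, expr = _toy(d, np.ones(40))
    with pytest.warns(UserWarning):
        out = assoc.scan_gene(gm, expr, "g1")
    assert (out["p"] == 1.0).all() and (out["r2"] == 0.0).all()


def test_scan_null_p_uniform():
    """Independent expression against 1000 SNPs: p-values ~ Uniform(0, 1)."""
    rng = np.random.default_rng(2)
    d = rng.binomial(2, 0.3, size=(200, 1000)).astype(float)
    gm, expr = _toy(d, np.power(2.0, rng.normal(3, 1, 200)))
    out = assoc.scan_gene(gm, expr, "g1")
    ks = sps.kstest(out["p"], "uniform")
    assert ks.pvalue > 0.01


def test_scan_power_on_planted_effect():
    """beta = 1, noise SD 0.5, n = 300: the causal SNP clears 1e-6."""
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.3, size=(300, 1)).astype(float)
        y = 3 + d[:, 0] + rng.normal(0, 0.5, 300)
        gm, expr = _toy(d, np.power(2.0, y))
        out = assoc.scan_gene(gm, expr, "g1")
        hits += out["p"].iloc[0] <= 1e-6
    assert hits == 5


def test_scan_with_missing_dosages():
    rng = np.random.default_rng(3)
    d = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
    y = 3 + d[:, 0] + rng.normal(0, 0.5, 100)
    d[rng.choice(100, 10, replace=False), 0] = np.nan
    gm, expr = _toy(d, np.power(2.0, y))
    out = assoc.scan_gene(gm, expr, "g1")
    assert out["p"].iloc[0] < 1e-6  # still detected on the complete pairs


def test_significant_snps_matches_filter():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({"p": rng.uniform(0, 1, 50) ** 6})
    out = assoc.significant_snps(df, 1e-3)
    assert out["p"].tolist() == [p for p in df["p"] if p <= 1e-3]
    assert len(assoc.significant_snps(pd.DataFrame({"p": []}))) == 0
    assert len(assoc.significant_snps(pd.DataFrame({"p": [0.5] * 5}))) == 0


def test_ld_r2_values():
    assert assoc.ld_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)
    assert assoc.ld_r2([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)
    a, b = [0, 1, 2, 1, 0], [0, 1, 1, 2, 0]
    assert assoc.ld_r2(a, b) == pytest.approx(pearson_r2_brute(
        np.array(a, float), np.array(b, float)))
    with pytest.warns(UserWarning):
        assert assoc.ld_r2([1, 1, 1, 1], [0, 1, 2, 0]) == 0.0


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

def _block_dosages(rng, n_acc, block_sizes):
    cols, block_of = [], []
    for b, size in enumerate(block_sizes):
        founder = rng.binomial(2, rng.uniform(0.15, 0.4), n_acc).astype(float)
        for _ in range(size):
            col = founder.copy()
            m = rng.random(n_acc) < 0.05
            col[m] = rng.binomial(2, 0.3, m.sum())
            cols.append(col)
            block_of.append(b)
    return np.column_stack(cols), block_of


def test_clump_single_and_block_absorption():
    rng = np.random.default_rng(5)
    d, _ = _block_dosages(rng, 80, [2])
    snps = pd.DataFrame({"chrom": ["A01"] * 2, "pos": [0, 100],
                         "ref": "A", "alt": "G"})
    gm = GenotypeMatrix([f"s{i}" for i in range(80)], snps, d)
    one = pd.DataFrame({"gene_id": ["g"], "snp": [0], "chrom": ["A01"],
                        "pos": [0], "beta": [1.0], "r2": [0.5], "p": [1e-9]})
    recs = assoc.clump(one, gm)
    assert len(recs) == 1 and recs[0].lead_idx == 0
    two = pd.DataFrame({"gene_id": ["g"] * 2, "snp": [0, 1],
                        "chrom": ["A01"] * 2, "pos": [0, 100],
                        "beta": [1.0, 0.9], "r2": [0.5, 0.4],
                        "p": [1e-9, 1e-8]})
    recs = assoc.clump(two, gm)
    assert len(recs) == 1 and recs[0].member_idx == [0, 1]


@pytest.mark.parametrize("seed", range(20))
def test_clump_matches_brute_force(seed):
    """Greedy absorption equals an explicit-loop reimplementation on random
    multi-block instances."""
    rng = np.random.default_rng(100 + seed)
    d, _ = _block_dosages(rng, 60, [4, 3, 3])
    m = d.shape[1]
    snps = pd.DataFrame({"chrom": ["A01"] * m, "pos": np.arange(m) * 50,
                         "ref": "A", "alt": "G"})
    gm = GenotypeMatrix([f"s{i}" for i in range(60)], snps, d)
    sig = pd.DataFrame({
        "gene_id": ["g"] * m, "snp": np.arange(m),
        "chrom": ["A01"] * m, "pos": np.arange(m) * 50,
        "beta": rng.normal(size=m), "r2": rng.uniform(0.2, 0.9, m),
        "p": rng.uniform(0, 1e-6, m)})
    got = [frozenset(r.member_idx) for r in assoc.clump(sig, gm)]
    want = clump_brute(sig, d, 0.2)
    assert got == want
    # partition property: every significant SNP in exactly one record
    flat = [s for g in got for s in g]
    assert sorted(flat) == list(range(m))


def test_clump_leads_pairwise_unlinked(demo_gm, demo_records):
    recs1, _ = demo_records
    by_gene = {}
    for r in recs1:
        by_gene.setdefault(r.gene_id, []).append(r)
    checked = 0
    for gene, recs in by_gene.items():
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                r2 = assoc.ld_r2(demo_gm.dosages[:, recs[i].lead_idx],
                                 demo_gm.dosages[:, recs[j].lead_idx])
                assert r2 <= 0.2
                checked += 1
    assert checked > 0 or len(by_gene) > 0


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _gene():
    return GeneModel("g", "A01", "+", 1_000_000, 1_002_000, 1_000_000)


def _rec(chrom, pos, stage=STAGE1):
    return assoc.EqtlRecord("g", stage, chrom, pos, 0, [0], 1e-9, 0.5, 1.0)


def test_classify_eqtl_rules_and_boundaries():
    g = _gene()
    assert assoc.classify_eqtl(_rec("A01", 1_001_000), g) == "local"
    assert assoc.classify_eqtl(_rec("C01", 1_001_000), g) == "distant"
    # boundary inclusive on both sides of the 500-kb window
    assert assoc.classify_eqtl(_rec("A01", 500_000), g) == "local"
    assert assoc.classify_eqtl(_rec("A01", 499_999), g) == "distant"
    assert assoc.classify_eqtl(_rec("A01", 1_501_999), g) == "local"
    assert assoc.classify_eqtl(_rec("A01", 1_502_000), g) == "distant"


def test_planted_categories_recovered(demo_study, demo_records):
    """Planted locals classify local; hotspot-target associations at the
    regulator locus classify distant."""
    recs1, _ = demo_records
    by_gene = {}
    for r in recs1:
        by_gene.setdefault(r.gene_id, []).append(r)
    n_local_ok = sum(
        any(r.category == "local" and abs(r.pos - x.pos) <= 100_000
            for r in by_gene.get(x.gene_id, []))
        for x in demo_study.truth.locals if STAGE1 in x.stages)
    assert n_local_ok / len(demo_study.truth.locals) >= 0.95
    hsp = demo_study.truth.hotspots[0]
    n_distant_ok = sum(
        any(r.category == "distant" and r.chrom == hsp.chrom
            for r in by_gene.get(t, []))
        for t in hsp.targets)
    assert n_distant_ok / len(hsp.targets) >= 0.95


def test_egene_summary(demo_records):
    recs1, _ = demo_records
    df = assoc.egene_summary(recs1)
    assert (df["n_eqtl"] == df["n_local"] + df["n_distant"]).all()
    assert df["n_eqtl"].sum() == len(recs1)


def test_stage_overlap_trivial_cases():
    a = [_rec("A01", 100), _rec("A01", 5_000_000)]
    same = [_rec("A01", 100, "40DAF"), _rec("A01", 5_000_000, "40DAF")]
    out = assoc.stage_overlap(a, same)
    assert (out["status"] == "both").all()
    b = [_rec("C02", 100, "40DAF")]
    out = assoc.stage_overlap(a, b)
    assert set(out.loc[out["stage"] == STAGE1, "status"]) == {"s1_only"}
    assert set(out.loc[out["stage"] == "40DAF", "status"]) == {"s2_only"}


def test_stage_specific_eqtls_labelled_s1_only(demo_study, demo_records):
    recs1, _ = demo_records
    specific = [x for x in demo_study.truth.locals if x.stages == [STAGE1]]
    assert specific
    ok = 0
    for x in specific:
        for r in recs1:
            if (r.gene_id == x.gene_id and r.category == "local"
                    and abs(r.pos - x.pos) <= 100_000):
                ok += r.overlap_status == "s1_only"
                break
    assert ok / len(specific) >= 0.9


# ---------------------------------------------------------------------------
# TWAS
# ---------------------------------------------------------------------------

def test_twas_noiseless_single_gene(demo_study):
    expr = demo_study.expr1
    trait = pd.Series(expr.gene_vector(expr.gene_ids[3]),
                      index=expr.accessions)
    out = assoc.twas(expr, trait)
    top = out.sort_values("p").iloc[0]
    assert top["gene_id"] == expr.gene_ids[3]
    assert top["q"] <= 0.05 and top["significant"]


def test_twas_planted_recovery_and_fdr():
    """All planted causal genes recovered; mean empirical FDR <= 0.1 over
    seeds."""
    from polyeqtl.simulate import SimConfig, simulate_study

    recov, fdrs = [], []
    for seed in (1, 2, 3):
        study = simulate_study(SimConfig(seed=seed))
        out = assoc.twas(study.expr1, study.trait)
        sig = set(out.loc[out["significant"], "gene_id"])
        causal = {t["gene_id"] for t in study.truth.trait_causal}
        recov.append(len(sig & causal) / len(causal))
        fdrs.append(len(sig - causal) / len(sig) if sig else 0.0)
    assert min(recov) == 1.0
    assert np.mean(fdrs) <= 0.1


def test_twas_q_monotone_and_bounded(demo_study):
    out = assoc.twas(demo_study.expr1, demo_study.trait)
    assert (out["q"] >= out["p"] - 1e-12).all()
    # q is monotone non-decreasing in p after BH
    srt = out.sort_values("p")
    assert (np.diff(srt["q"].to_numpy()) >= -1e-12).all()
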