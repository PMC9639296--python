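"""I/O round trips, coordinate conventions and the MAF filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyeqtl import formats_io as fio

from oracles import maf_brute, merge_intervals_brute


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=A01,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
A01\t101\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
A01\t202\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
A01\t303\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t1/1\t0/0
A01\t404\t.\tT\tTA\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
A01\t505\t.\tA\tC,G\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
A01\t606\t.\tC\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t0/1
"""


def test_vcf_hand_transcription(tmp_path):
    """GT decoding matches a by-eye transcription; non-SNP and multi-allelic
    records are skipped."""
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TEXT)
    with pytest.warns(UserWarning):
        gm = fio.read_vcf(path, on_multiallelic="skip")
    assert gm.accessions == ["s1", "s2", "s3"]
    # indel (POS 404) and multi-allelic (POS 505) rows are gone
    assert gm.snps["pos"].tolist() == [100, 201, 302, 605]  # 0-based
    expected = np.array(
        [[0, np.nan, 2, 1],
         [1, 0, 2, 1],
         [2, 1, 0, 1]], dtype=float)
    np.testing.assert_array_equal(np.isnan(gm.dosages), np.isnan(expected))
    np.testing.assert_array_equal(np.nan_to_num(gm.dosages),
                                  np.nan_to_num(expected))


def test_vcf_multiallelic_error(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TEXT)
    with pytest.raises(fio.FormatError):
        fio.read_vcf(path, on_multiallelic="error")


def test_vcf_round_trip(tmp_path, demo_study):
    gm = demo_study.genotypes
    fio.write_vcf(gm, tmp_path / "rt.vcf", demo_study.genome)
    back = fio.read_vcf(tmp_path / "rt.vcf")
    assert back.accessions == gm.accessions
    pd.testing.assert_frame_equal(back.snps, gm.snps)
    np.testing.assert_array_equal(back.dosages, gm.dosages)


# ---------------------------------------------------------------------------
# GFF3 / BED / TSV
# ---------------------------------------------------------------------------

def test_gff3_strand_rule_and_round_trip(tmp_path):
    """A minus-strand gene spanning 1-based 101..200 has its TSS at 200."""
    text = (
        "##gff-version 3\n"
        "##sequence-region A01 1 50000\n"
        "##sequence-region C01 1 50000\n"
        "A01\tsrc\tgene\t101\t200\t.\t-\t.\tID=g1\n"
        "A01\tsrc\tgene\t301\t400\t.\t+\t.\tID=g2\n"
        "C01\tsrc\tgene\t501\t700\t.\t+\t.\tID=g3\n"
    )
    path = tmp_path / "g.gff3"
    path.write_text(text)
    genome = fio.read_gff3(path)
    g1 = genome["g1"]
    assert (g1.start, g1.end) == (100, 200)  # 0-based half-open
    assert g1.tss == 199                     # = 1-based 200
    assert genome["g2"].tss == 300
    assert genome.chrom_lengths == {"A01": 50000, "C01": 50000}
    assert [g.ordinal for g in genome.genes] == [0, 1, 0]
    fio.write_gff3(genome, tmp_path / "rt.gff3")
    back = fio.read_gff3(tmp_path / "rt.gff3")
    assert back.genes_df.equals(genome.genes_df)


def test_bed_convention_and_round_trip(tmp_path):
    """BED line 'A09 100 200' covers 0-based 100..199 = 1-based 101..200."""
    path = tmp_path / "x.bed"
    path.write_text("A09\t100\t200\n")
    iv = fio.read_bed(path)
    assert iv.contains(["A09", "A09", "A09"], [100, 199, 200]).tolist() == [
        True, True, False]
    assert not iv.contains(["A09"], [99])[0]
    fio.write_bed(iv, tmp_path / "rt.bed")
    back = fio.read_bed(tmp_path / "rt.bed")
    pd.testing.assert_frame_equal(back.df, iv.df[["chrom", "start", "end"]])


def test_bed_bounds_check(tmp_path, demo_study):
    path = tmp_path / "bad.bed"
    path.write_text("A01\t100\t999999999\n")
    with pytest.raises(fio.FormatError):
        fio.read_bed(path, demo_study.genome)


def test_expression_trait_similarity_round_trips(tmp_path, demo_study):
    fio.write_expression_tsv(demo_study.expr1, tmp_path / "e.tsv")
    back = fio.read_expression_tsv(tmp_path / "e.tsv", stage=demo_study.expr1.stage)
    assert back.accessions == demo_study.expr1.accessions
    assert back.gene_ids == demo_study.expr1.gene_ids
    np.testing.assert_allclose(back.values, demo_study.expr1.values, rtol=1e-4)

    fio.write_trait_tsv(demo_study.trait, tmp_path / "t.tsv")
    t = fio.read_trait_tsv(tmp_path / "t.tsv")
    np.testing.assert_allclose(t.to_numpy(), demo_study.trait.to_numpy(),
                               atol=1e-5)

    fio.write_similarity_tsv(demo_study.similarity, tmp_path / "s.tsv")
    s = fio.read_similarity_tsv(tmp_path / "s.tsv")
    assert len(s) == len(demo_study.similarity)


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def _gm(dosages):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    snps = pd.DataFrame({
        "chrom": ["A01"] * m, "pos": np.arange(m) * 100,
        "ref": ["A"] * m, "alt": ["G"] * m})
    return fio.GenotypeMatrix([f"s{i}" for i in range(n)], snps, dosages)


def test_filter_maf_edge_cases():
    # monomorphic SNP removed; a single heterozygote among 10 accessions is
    # MAF 0.05 exactly and removed at the strict > 0.05 threshold
    col_mono = [0] * 10
    col_edge = [1] + [0] * 9
    col_keep = [1, 1, 2] + [0] * 7  # MAF 0.2
    gm = _gm(np.array([col_mono, col_edge, col_keep]).T)
    out = gm.filter_maf(0.05)
    assert out.n_snps == 1
    assert out.snps["pos"].tolist() == [200]


def test_filter_maf_matches_brute_force():
    rng = np.random.default_rng(3)
    dosages = rng.integers(0, 3, size=(40, 60)).astype(float)
    gm = _gm(dosages)
    out = gm.filter_maf(0.1)
    keep = maf_brute(dosages) > 0.1
    assert out.n_snps == int(keep.sum())
    np.testing.assert_array_equal(out.dosages, dosages[:, keep])


def test_filter_maf_idempotent():
    rng = np.random.default_rng(4)
    gm = _gm(rng.integers(0, 3, size=(30, 40)).astype(float))
    once = gm.filter_maf(0.1)
    twice = once.filter_maf(0.1)
    np.testing.assert_array_equal(once.dosages, twice.dosages)


# ---------------------------------------------------------------------------
# IntervalSet properties
# ---------------------------------------------------------------------------

interval_lists = st.lists(
    st.tuples(st.integers(0, 300), st.integers(1, 60)), min_size=1, max_size=25
)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(interval_lists)
def test_merge_matches_mask_union_and_is_idempotent(raw):
    df = pd.DataFrame(
        [("A01", s, s + l) for s, l in raw], columns=["chrom", "start", "end"]
    )
    iv = fio.IntervalSet(df)
    merged = iv.merged()
    pd.testing.assert_frame_equal(merged.df, merge_intervals_brute(df))
    pd.testing.assert_frame_equal(merged.merged().df, merged.df)
    assert merged.total_coverage() <= int((df["end"] - df["start"]).sum())


def test_contains_matches_brute():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({
        "chrom": rng.choice(["A01", "C02"], 30),
        "start": rng.integers(0, 5000, 30)})
    df["end"] = df["start"] + rng.integers(1, 400, 30)
    iv = fio.IntervalSet(df)
    chroms = rng.choice(["A01", "C02", "X"], 200)
    pos = rng.integers(0, 6000, 200)
    got = iv.contains(chroms, pos)
    for c, p, g in zip(chroms, pos, got):
        want = any(
            (r["chrom"] == c and r["start"] <= p < r["end"])
            for _, r in df.iterrows())
        assert g == want


def test_genome_validation():
    chroms = pd.DataFrame(
        {"name": ["A01"], "length": [1000], "subgenome": ["An"]})
    with pytest.raises(ValueError):
        fio.Genome(chroms, [fio.GeneModel("g", "A01", "+", 900, 1200, 900)])
    with pytest.raises(ValueError):
        fio.GeneModel("g", "A01", "+", 100, 100, 100)   # empty interval
    with pytest.raises(ValueError):
        fio.GeneModel("g", "A01", "+", 100, 200, 300)   # TSS outside body
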