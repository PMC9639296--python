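"""Core domain containers and file I/O.

All in-memory coordinates are 0-based, half-open. Conversion to and from the
1-based inclusive conventions of VCF/GFF3 happens only inside the readers and
writers in this module; BED is already half-open and passes through unchanged.

Containers
----------
``Genome``            chromosomes (with An/Cn subgenome tags) + gene models
``GenotypeMatrix``    accessions x SNPs additive dosage codes {0,1,2}
``ExpressionMatrix``  accessions x genes TPM values for one developmental stage
``IntervalSet``       genomic intervals (e.g. ATAC open-chromatin regions)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBGENOMES = ("An", "Cn")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Genome / gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene locus. ``start``/``end`` are 0-based half-open; ``tss`` is the
    0-based position of the transcription start (start on +, end-1 on -)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    is_tf: bool = False
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not (self.start < self.end):
            raise ValueError(f"empty interval for gene {self.gene_id}")
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"TSS outside gene body for {self.gene_id}")

    def distance_to(self, pos: int) -> int:
        """bp distance from a point to the gene body (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


def subgenome_of(chrom: str) -> str:
    """Infer the subgenome tag from a chromosome name (A* -> An, C* -> Cn)."""
    if chrom.upper().startswith("A"):
        return "An"
    if chrom.upper().startswith("C"):
        return "Cn"
    raise ValueError(f"cannot infer subgenome for chromosome {chrom!r}")


@dataclass
class Genome:
    """Chromosome table plus gene models with per-chromosome ordinal indices.

    ``chromosomes`` has columns name, length, subgenome. Gene ordinals are
    (re)assigned on construction: consecutive from 0 in coordinate order
    within each chromosome.
    """

    chromosomes: pd.DataFrame
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        names = list(self.chromosomes["name"])
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = dict(zip(self.chromosomes["name"], self.chromosomes["length"]))
        ordered: list[GeneModel] = []
        order = {n: i for i, n in enumerate(names)}
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")
            ordered.append(g)
        ordered.sort(key=lambda g: (order[g.chrom], g.start, g.gene_id))
        out: list[GeneModel] = []
        counter: dict[str, int] = {}
        for g in ordered:
            k = counter.get(g.chrom, 0)
            out.append(replace(g, ordinal=k))
            counter[g.chrom] = k + 1
        self.genes = out
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")

    # -- accessors ---------------------------------------------------------

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(zip(self.chromosomes["name"], self.chromosomes["length"]))

    @property
    def total_length(self) -> int:
        return int(self.chromosomes["length"].sum())

    @property
    def genes_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "is_tf": [g.is_tf for g in self.genes],
                "ordinal": [g.ordinal for g in self.genes],
            }
        )

    def tf_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.is_tf]

    def with_tf_flags(self, tf_ids: Iterable[str]) -> "Genome":
        tfs = set(tf_ids)
        genes = [replace(g, is_tf=g.gene_id in tfs) for g in self.genes]
        return Genome(self.chromosomes.copy(), genes)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Additive dosage matrix (accessions x SNPs).

    ``snps`` columns: chrom, pos (0-based), ref, alt, sorted by (chrom, pos)
    in the chromosome order of the genome they came from. ``dosages`` is a
    float array with values in {0, 1, 2} and NaN for missing calls.
    """

    accessions: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        if self.dosages.shape != (len(self.accessions), len(self.snps)):
            raise ValueError("dosage matrix shape does not match accessions x snps")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("dosages must be 0/1/2 or NaN")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, ignoring missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        freq = np.nan_to_num(freq, nan=0.0)
        return np.minimum(freq, 1.0 - freq)

    def filter_maf(self, maf_min: float) -> "GenotypeMatrix":
        """Keep SNPs with MAF strictly greater than ``maf_min``."""
        keep = self.maf() > maf_min
        if not keep.any():
            warnings.warn("MAF filter removed every SNP", stacklevel=2)
        return GenotypeMatrix(
            list(self.accessions), self.snps.loc[keep], self.dosages[:, keep]
        )

    def mean_imputed(self) -> "GenotypeMatrix":
        """Replace missing dosages by the per-SNP mean (optional convenience)."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            col_mean = np.nanmean(d, axis=0)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
            # keep the 0/1/2-or-NaN contract by rounding imputed cells
            d[idx] = np.clip(np.round(d[idx]), 0, 2)
        return GenotypeMatrix(list(self.accessions), self.snps.copy(), d)

    def subset_accessions(self, accs: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.accessions)}
        idx = [pos[a] for a in accs]
        return GenotypeMatrix(list(accs), self.snps.copy(), self.dosages[idx])


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """TPM expression values (accessions x genes) for one stage label."""

    accessions: list[str]
    gene_ids: list[str]
    values: np.ndarray
    stage: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.accessions), len(self.gene_ids)):
            raise ValueError("expression shape does not match accessions x genes")
        if (self.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        self._col = {g: j for j, g in enumerate(self.gene_ids)}

    def col(self, gene_id: str) -> int:
        return self._col[gene_id]

    def log2p1(self) -> np.ndarray:
        return np.log2(self.values + 1.0)

    def gene_vector(self, gene_id: str, log: bool = True) -> np.ndarray:
        v = self.values[:, self._col[gene_id]]
        return np.log2(v + 1.0) if log else v

    def subset_accessions(self, accs: Sequence[str]) -> "ExpressionMatrix":
        pos = {a: i for i, a in enumerate(self.accessions)}
        idx = [pos[a] for a in accs]
        return ExpressionMatrix(list(accs), list(self.gene_ids), self.values[idx], self.stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accessions, columns=self.gene_ids)


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """A set of genomic intervals in 0-based half-open convention.

    ``df`` columns: chrom, start, end (extra metadata columns are carried
    along untouched). ``merged`` collapses overlapping/book-ended intervals;
    ``contains`` does vectorized point membership against the merged set.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("intervals must satisfy start < end")
        self._merged_cache: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.df)

    def merged(self, gap: int = 0) -> "IntervalSet":
        """Union of intervals; intervals separated by <= ``gap`` bp are joined."""
        rows = []
        for chrom, sub in self.df.sort_values(["chrom", "start", "end"]).groupby(
            "chrom", sort=True
        ):
            cur_s = cur_e = None
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                if cur_s is None:
                    cur_s, cur_e = int(s), int(e)
                elif s <= cur_e + gap:
                    cur_e = max(cur_e, int(e))
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = int(s), int(e)
            if cur_s is not None:
                rows.append((chrom, cur_s, cur_e))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def _merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._merged_cache is None:
            m = self.merged()
            cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, sub in m.df.groupby("chrom", sort=True):
                cache[str(chrom)] = (
                    sub["start"].to_numpy(int),
                    sub["end"].to_numpy(int),
                )
            self._merged_cache = cache
        return self._merged_cache

    def contains(self, chroms: Sequence[str], positions: Sequence[int]) -> np.ndarray:
        """Membership of 0-based points: inside iff start <= p < end."""
        cache = self._merged_arrays()
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=int)
        out = np.zeros(len(positions), dtype=bool)
        for chrom in np.unique(chroms):
            arr = cache.get(str(chrom))
            if arr is None:
                continue
            starts, ends = arr
            mask = chroms == chrom
            p = positions[mask]
            i = np.searchsorted(starts, p, side="right") - 1
            ok = (i >= 0) & (p < ends[np.clip(i, 0, len(ends) - 1)])
            out[mask] = ok
        return out

    def coverage(self) -> dict[str, int]:
        m = self.merged().df
        return {
            str(c): int((sub["end"] - sub["start"]).sum())
            for c, sub in m.groupby("chrom", sort=True)
        }

    def total_coverage(self) -> int:
        return sum(self.coverage().values())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, on_multiallelic: str = "error") -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a dosage matrix.

    ``GT`` fields map to 0/1/2 (count of ALT alleles); ``./.`` becomes NaN.
    Non-SNP ALT records are skipped with a counted warning; multi-allelic
    records raise (``on_multiallelic='error'``) or are skipped (``'skip'``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows, cols, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            if on_multiallelic == "error":
                raise FormatError(
                    f"multi-allelic record at {var.CHROM}:{var.POS} in {path}"
                )
            skipped += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
        cols.append(dos)
    if skipped:
        warnings.warn(f"read_vcf: skipped {skipped} non-biallelic-SNP records")
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = (
        np.column_stack(cols) if cols else np.zeros((len(accessions), 0))
    )
    return GenotypeMatrix(accessions, snps, dosages)


_DOS_TO_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | Path, genome: Genome | None = None) -> None:
    """Write a minimal VCF 4.2 file (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if genome is not None:
            for _, row in genome.chromosomes.iterrows():
                fh.write(f"##contig=<ID={row['name']},length={row['length']}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accessions)
            + "\n"
        )
        for j, (_, snp) in enumerate(gm.snps.iterrows()):
            gts = [
                _DOS_TO_GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{snp['chrom']}\t{int(snp['pos']) + 1}\t.\t{snp['ref']}\t"
                f"{snp['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_gff3(path: str | Path) -> Genome:
    """Read gene features and ##sequence-region pragmas from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    chrom_rows = []
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            name, _one, end = parts[1], int(parts[2]), int(parts[3])
            chrom_rows.append((name, end, subgenome_of(name)))
    if not chrom_rows:
        raise FormatError(f"no ##sequence-region directives in {path}")
    chroms = pd.DataFrame(chrom_rows, columns=["name", "length", "subgenome"])
    genes = []
    for feat in db.features_of_type("gene"):
        start0, end0 = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        tss = start0 if feat.strand == "+" else end0 - 1
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=start0,
                end=end0,
                tss=tss,
            )
        )
    return Genome(chroms, genes)


def write_gff3(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in genome.chromosomes.iterrows():
            fh.write(f"##sequence-region {row['name']} 1 {row['length']}\n")
        for g in genome.genes:
            fh.write(
                f"{g.chrom}\tpolyeqtl\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_bed(path: str | Path, genome: Genome | None = None) -> IntervalSet:
    """Read a BED3+ file (already 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    iv = IntervalSet(df)
    if genome is not None:
        lengths = genome.chrom_lengths
        for _, row in iv.df.iterrows():
            if row["chrom"] not in lengths or row["end"] > lengths[row["chrom"]]:
                raise FormatError(
                    f"interval {row['chrom']}:{row['start']}-{row['end']} "
                    f"outside chromosome bounds in {path}"
                )
    return iv


def write_bed(iv: IntervalSet, path: str | Path) -> None:
    iv.df.to_csv(path, sep="\t", header=False, index=False)


def read_expression_tsv(path: str | Path, stage: str = "") -> ExpressionMatrix:
    """TSV with header row of gene ids and first column of accession ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        [str(a) for a in df.index], [str(g) for g in df.columns],
        df.to_numpy(float), stage=stage,
    )


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="accession", float_format="%.6f")


def read_trait_tsv(path: str | Path, trait: str | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = trait if trait is not None else df.columns[0]
    s = df[col].astype(float)
    s.index = s.index.astype(str)
    return s


def write_trait_tsv(trait: pd.Series, path: str | Path, name: str = "trait") -> None:
    trait.rename(name).to_frame().to_csv(path, sep="\t", index_label="accession",
                                         float_format="%.6f")


def read_tf_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_tf_list(tf_ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tf_ids:
            fh.write(f"{t}\n")


def read_similarity_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"an_gene", "cn_gene", "score"}
    if not expected.issubset(df.columns):
        raise FormatError(f"similarity table needs columns {sorted(expected)}")
    return df


def write_similarity_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic result-table writer (TSV with header)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
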