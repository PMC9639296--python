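"""Synthetic allotetraploid eQTL study generator.

Builds a two-subgenome (An/Cn) genome with positionally matched homoeologs,
LD-block genotypes, two-stage expression with planted local eQTLs, a planted
distant-eQTL hotspot (a cis-driven TF regulator propagating into many target
genes), homoeolog pairs with optional negative feedback, co-expressed
adjacent gene pairs, open-chromatin regions enriched over causal SNPs, and a
quantitative trait driven by a small causal gene set.

Every quantity the downstream modules try to recover is recorded in
``GroundTruth``, so recovery metrics never need to re-derive the planting.
All randomness flows from a single ``numpy`` Generator seeded by
``SimConfig.seed``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    ExpressionMatrix,
    GeneModel,
    Genome,
    GenotypeMatrix,
    IntervalSet,
    write_bed,
    write_expression_tsv,
    write_gff3,
    write_similarity_tsv,
    write_tf_list,
    write_trait_tsv,
    write_vcf,
)

STAGE1 = "20DAF"
STAGE2 = "40DAF"


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic population.

    Defaults are the documented demo conditions: 300 accessions, 4
    chromosomes of 12 Mb (2 per subgenome), planted local effect size 1.0,
    distant (hotspot / homoeolog-driver) effect 0.8, expression noise SD 0.5,
    feedback strength -0.8 and a 5x odds of causal SNPs falling in open
    chromatin.
    """

    seed: int = 1
    n_accessions: int = 300
    chroms_per_subgenome: int = 2
    chrom_length: int = 12_000_000
    genes_per_chrom: int = 120
    snps_per_chrom: int = 240
    ld_block_len: int = 100_000
    maf_range: tuple[float, float] = (0.10, 0.45)
    snp_mutation_rate: float = 0.03
    tf_fraction: float = 0.10
    # local eQTLs
    n_local_eqtl: int = 20
    local_effect: float = 1.0
    stage_specific_fraction: float = 0.3
    # distant hotspot
    n_hotspots: int = 1
    hotspot_targets: int = 40
    distant_effect: float = 0.8
    regulator_cis_effect: float = 1.0
    # homoeolog pairs
    n_feedback_pairs: int = 20
    n_nolocal_pairs: int = 20
    feedback_strength: float = -0.8
    feedback_tf_odds: float = 2.0
    hgp_window: int = 150_000
    n_biased_pairs: int = 25
    bias_shift: float = 1.0
    # adjacent co-expression
    n_adjacent_pairs: int = 45
    shared_factor_sd: float = 0.8
    state_coupling_sd: float = 0.7
    # open chromatin
    ocr_fraction: float = 0.10
    ocr_causal_enrichment: float = 5.0
    ocr_len_range: tuple[int, int] = (800, 2200)
    ocr_effect_boost: float = 1.5
    # trait
    n_trait_causal: int = 5
    trait_effect: float = 1.0
    trait_noise_sd: float = 1.0
    # expression
    noise_sd: float = 0.5
    base_expr_mean: float = 3.0
    base_expr_sd: float = 1.0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if not (-1.0 <= self.feedback_strength <= 0.0):
            raise ValueError("feedback_strength must lie in [-1, 0]")
        for frac in (self.stage_specific_fraction, self.ocr_fraction, self.tf_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        n_genes = 2 * self.chroms_per_subgenome * self.genes_per_chrom
        demand = (
            self.n_hotspots * (1 + self.hotspot_targets)
            + self.n_local_eqtl
            + 2 * (self.n_feedback_pairs + self.n_nolocal_pairs + self.n_biased_pairs)
            + 2 * self.n_adjacent_pairs
        )
        if demand > n_genes:
            raise ValueError(
                f"planted structure needs {demand} genes but genome has {n_genes}"
            )
        if self.n_trait_causal > self.n_local_eqtl:
            raise ValueError("trait causal genes are drawn from the local-eQTL set")


# ---------------------------------------------------------------------------
# Ground truth records
# ---------------------------------------------------------------------------

@dataclass
class PlantedLocal:
    gene_id: str
    snp_idx: int
    chrom: str
    pos: int
    beta: float
    stages: list[str]
    in_ocr: bool


@dataclass
class PlantedHotspot:
    regulator_gene: str
    cis_snp_idx: int
    chrom: str
    pos: int
    targets: list[str]
    coefs: list[float]
    in_ocr: bool


@dataclass
class PlantedHGP:
    an_gene: str
    cn_gene: str
    direction: str  # "An_reg_Cn" | "Cn_reg_An"
    driver_snp_idx: int
    driver_pos: int
    driver_chrom: str
    feedback: bool
    local_snp_idx: int | None
    driver_in_ocr: bool


@dataclass
class PlantedAdjacent:
    gene_a: str
    gene_b: str
    snp_a: int
    snp_b: int
    pattern: str  # both_open | one_open | both_closed


@dataclass
class GroundTruth:
    """Exhaustive record of everything planted by the simulator."""

    locals: list[PlantedLocal] = field(default_factory=list)
    hotspots: list[PlantedHotspot] = field(default_factory=list)
    hgps: list[PlantedHGP] = field(default_factory=list)
    biased_pairs: list[dict] = field(default_factory=list)
    adjacent_pairs: list[PlantedAdjacent] = field(default_factory=list)
    trait_causal: list[dict] = field(default_factory=list)
    ocr_flags: dict[int, bool] = field(default_factory=dict)

    def causal_snp_indices(self) -> list[int]:
        return sorted(self.ocr_flags)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "locals": [asdict(x) for x in self.locals],
            "hotspots": [asdict(x) for x in self.hotspots],
            "hgps": [asdict(x) for x in self.hgps],
            "biased_pairs": self.biased_pairs,
            "adjacent_pairs": [asdict(x) for x in self.adjacent_pairs],
            "trait_causal": self.trait_causal,
            "ocr_flags": {str(k): v for k, v in self.ocr_flags.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            locals=[PlantedLocal(**x) for x in raw["locals"]],
            hotspots=[PlantedHotspot(**x) for x in raw["hotspots"]],
            hgps=[PlantedHGP(**x) for x in raw["hgps"]],
            biased_pairs=raw["biased_pairs"],
            adjacent_pairs=[PlantedAdjacent(**x) for x in raw["adjacent_pairs"]],
            trait_causal=raw["trait_causal"],
            ocr_flags={int(k): v for k, v in raw["ocr_flags"].items()},
        )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SimConfig, rng: np.random.Generator) -> Genome:
    """Paired An/Cn chromosomes with positionally matched gene sets.

    Gene k on chromosome A0j and gene k on C0j occupy the same slot, so each
    (A, C) index pair is a true homoeolog pair. Roughly ``tf_fraction`` of
    slots are flagged as transcription factors, consistently across the two
    homoeologs of a slot.
    """
    cfg.validate()
    chrom_rows = []
    for j in range(cfg.chroms_per_subgenome):
        chrom_rows.append((f"A{j + 1:02d}", cfg.chrom_length, "An"))
    for j in range(cfg.chroms_per_subgenome):
        chrom_rows.append((f"C{j + 1:02d}", cfg.chrom_length, "Cn"))
    chroms = pd.DataFrame(chrom_rows, columns=["name", "length", "subgenome"])

    genes: list[GeneModel] = []
    slot = cfg.chrom_length // (cfg.genes_per_chrom + 1)
    for j in range(cfg.chroms_per_subgenome):
        # shared per-slot randomness so homoeolog slots line up positionally
        jitters = rng.integers(-slot // 4, slot // 4, size=cfg.genes_per_chrom)
        lengths = rng.integers(1500, 4000, size=cfg.genes_per_chrom)
        strands = rng.choice(["+", "-"], size=cfg.genes_per_chrom)
        tf_flags = rng.random(cfg.genes_per_chrom) < cfg.tf_fraction
        for sub, prefix in (("An", "A"), ("Cn", "C")):
            chrom = f"{prefix}{j + 1:02d}"
            for i in range(cfg.genes_per_chrom):
                start = int((i + 1) * slot + jitters[i] - lengths[i] // 2)
                start = max(1000, min(start, cfg.chrom_length - 5000))
                end = start + int(lengths[i])
                strand = str(strands[i])
                tss = start if strand == "+" else end - 1
                genes.append(
                    GeneModel(
                        gene_id=f"Bna{chrom}g{i:04d}",
                        chrom=chrom,
                        strand=strand,
                        start=start,
                        end=end,
                        tss=tss,
                        is_tf=bool(tf_flags[i]),
                    )
                )
    return Genome(chroms, genes)


def homoeolog_slots(genome: Genome) -> list[tuple[str, str]]:
    """True positional homoeolog pairs (An gene id, Cn gene id)."""
    pairs = []
    an = [g for g in genome.genes if g.chrom.startswith("A")]
    for g in an:
        # BnaA01g0007 -> BnaC01g0007
        partner = g.gene_id.replace("Bna" + g.chrom, "Bna" + "C" + g.chrom[1:])
        if partner in genome:
            pairs.append((g.gene_id, partner))
    return pairs


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig, genome: Genome, rng: np.random.Generator) -> GenotypeMatrix:
    """Block-copy LD genotypes.

    SNPs within one ``ld_block_len`` window share a founder dosage vector;
    each SNP copies the founder and resamples a ``snp_mutation_rate``
    fraction of entries, giving high intra-block r-squared and essentially
    zero between blocks. Per-SNP empirical MAF is constrained to
    ``maf_range`` by rejection.
    """
    lo, hi = cfg.maf_range
    n = cfg.n_accessions
    accessions = [f"acc{i:04d}" for i in range(n)]
    snp_rows = []
    cols = []
    for _, crow in genome.chromosomes.iterrows():
        chrom = crow["name"]
        spacing = cfg.chrom_length // (cfg.snps_per_chrom + 1)
        positions = np.sort(
            (np.arange(1, cfg.snps_per_chrom + 1) * spacing
             + rng.integers(-spacing // 4, spacing // 4, size=cfg.snps_per_chrom))
        ).astype(int)
        blocks = positions // cfg.ld_block_len
        founder: np.ndarray | None = None
        cur_block = -1
        for pos, block in zip(positions, blocks):
            if block != cur_block or founder is None:
                p = rng.uniform(lo + 0.02, hi - 0.02)
                for _ in range(100):
                    founder = rng.binomial(2, p, size=n).astype(float)
                    f = founder.mean() / 2
                    if lo < min(f, 1 - f) < hi:
                        break
                cur_block = block
            col = founder.copy()
            for _ in range(100):
                mask = rng.random(n) < cfg.snp_mutation_rate
                trial = founder.copy()
                trial[mask] = rng.binomial(2, founder.mean() / 2, size=int(mask.sum()))
                f = trial.mean() / 2
                if lo < min(f, 1 - f) < hi:
                    col = trial
                    break
            else:  # pragma: no cover - founder itself is always in range
                col = founder.copy()
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            snp_rows.append((chrom, int(pos), str(ref), str(alt)))
            cols.append(col)
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(accessions, snps, np.column_stack(cols))


def _snp_blocks(cfg: SimConfig, gm: GenotypeMatrix) -> np.ndarray:
    """Block key per SNP (chromosome-qualified)."""
    chrom_code = pd.factorize(gm.snps["chrom"])[0]
    return chrom_code * 10_000 + gm.snps["pos"].to_numpy(int) // cfg.ld_block_len


# ---------------------------------------------------------------------------
# Expression + planting
# ---------------------------------------------------------------------------

def _nearest_snp(gm: GenotypeMatrix, chrom: str, pos: int,
                 exclude: set[int] | None = None) -> int:
    sub = gm.snps.index[gm.snps["chrom"] == chrom]
    best, best_d = -1, None
    for idx in sub:
        if exclude and idx in exclude:
            continue
        d = abs(int(gm.snps.at[idx, "pos"]) - pos)
        if best_d is None or d < best_d:
            best, best_d = int(idx), d
    if best < 0:
        raise RuntimeError(f"no candidate SNP on {chrom}")
    return best


def _driver_snp(cfg: SimConfig, gm: GenotypeMatrix, blocks: np.ndarray,
                chrom: str, tss: int, avoid_block: int | None,
                window: int) -> int | None:
    """A SNP within +/-window of ``tss`` whose whole LD block also lies in
    the window (so whichever block-mate ends up as lead stays inside), in a
    block different from ``avoid_block``."""
    pos = gm.snps["pos"].to_numpy(int)
    on_chrom = (gm.snps["chrom"] == chrom).to_numpy()
    in_win = on_chrom & (np.abs(pos - tss) <= window)
    candidates = np.flatnonzero(in_win)
    best = None
    for idx in candidates:
        b = blocks[idx]
        if avoid_block is not None and b == avoid_block:
            continue
        mates = np.flatnonzero(blocks == b)
        contained = np.all(np.abs(pos[mates] - tss) <= window)
        if contained:
            return int(idx)
        if best is None:
            best = int(idx)
    return best


def simulate_expression(
    cfg: SimConfig, genome: Genome, gm: GenotypeMatrix, rng: np.random.Generator
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Two-stage TPM matrices with all planted genetic structure.

    Expression is built on a log2 scale (base ~ Normal(mean, sd), genetic
    effects additive in log space) and exponentiated, so the standard
    log2(TPM+1) transform downstream approximately recovers the linear
    model. A ``stage_specific_fraction`` of plain local eQTLs is present at
    stage 1 only; all other plantings act at both stages.
    """
    cfg.validate()
    n, genes = cfg.n_accessions, genome.genes
    gene_ids = [g.gene_id for g in genes]
    col = {g: j for j, g in enumerate(gene_ids)}
    blocks = _snp_blocks(cfg, gm)
    truth = GroundTruth()
    used_genes: set[str] = set()
    used_blocks: set[int] = set()
    q_in_ocr = (cfg.ocr_causal_enrichment * cfg.ocr_fraction) / (
        cfg.ocr_causal_enrichment * cfg.ocr_fraction + (1 - cfg.ocr_fraction)
    )

    def draw_ocr_flag() -> bool:
        return bool(rng.random() < q_in_ocr)

    # ---- hotspot regulator + targets -------------------------------------
    an_tfs = [
        g for g in genes
        if g.is_tf and g.chrom.startswith("A")
        and 1_500_000 < g.tss < cfg.chrom_length - 1_500_000
    ]
    if len(an_tfs) < cfg.n_hotspots:
        raise RuntimeError("not enough An-subgenome TF genes for hotspot regulators")
    regulators = list(rng.choice(np.arange(len(an_tfs)), size=cfg.n_hotspots,
                                 replace=False))
    non_tf_pool = [g for g in genes if not g.is_tf]
    for ridx in regulators:
        reg = an_tfs[int(ridx)]
        cis = _nearest_snp(gm, reg.chrom, reg.tss)
        used_genes.add(reg.gene_id)
        used_blocks.add(int(blocks[cis]))
        pool = [g for g in non_tf_pool
                if g.chrom != reg.chrom and g.gene_id not in used_genes]
        pick = rng.choice(np.arange(len(pool)), size=cfg.hotspot_targets, replace=False)
        targets = [pool[int(i)] for i in pick]
        coefs = (rng.choice([-1.0, 1.0], size=cfg.hotspot_targets)
                 * cfg.distant_effect)
        for t in targets:
            used_genes.add(t.gene_id)
        flag = draw_ocr_flag()
        truth.hotspots.append(
            PlantedHotspot(
                regulator_gene=reg.gene_id,
                cis_snp_idx=int(cis),
                chrom=reg.chrom,
                pos=int(gm.snps.at[cis, "pos"]),
                targets=[t.gene_id for t in targets],
                coefs=[float(c) for c in coefs],
                in_ocr=flag,
            )
        )
        truth.ocr_flags[int(cis)] = flag

    # ---- plain local eQTLs (distinct LD blocks) ---------------------------
    free = [g for g in genes if g.gene_id not in used_genes]
    order = rng.permutation(len(free))
    n_specific = int(round(cfg.stage_specific_fraction * cfg.n_local_eqtl))
    planted_local = 0
    for i in order:
        if planted_local >= cfg.n_local_eqtl:
            break
        g = free[int(i)]
        snp = _nearest_snp(gm, g.chrom, g.tss)
        if int(blocks[snp]) in used_blocks:
            continue
        used_blocks.add(int(blocks[snp]))
        used_genes.add(g.gene_id)
        flag = draw_ocr_flag()
        beta = float(rng.choice([-1.0, 1.0]) * cfg.local_effect)
        if flag:
            beta *= cfg.ocr_effect_boost
        # the first n_trait_causal drive the trait and stay present at both
        # stages; stage-specific effects come from the tail of the list
        stages = [STAGE1, STAGE2]
        truth.locals.append(
            PlantedLocal(g.gene_id, int(snp), g.chrom,
                         int(gm.snps.at[snp, "pos"]), beta, stages, flag)
        )
        truth.ocr_flags[int(snp)] = flag
        planted_local += 1
    if planted_local < cfg.n_local_eqtl:
        warnings.warn("could not place all requested local eQTLs in distinct blocks")
    for rec in truth.locals[len(truth.locals) - n_specific:]:
        rec.stages = [STAGE1]

    # ---- trait causal genes ----------------------------------------------
    for rec in truth.locals[: cfg.n_trait_causal]:
        truth.trait_causal.append(
            {"gene_id": rec.gene_id,
             "weight": float(rng.choice([-1.0, 1.0]) * cfg.trait_effect)}
        )

    # ---- homoeolog pairs --------------------------------------------------
    slots = homoeolog_slots(genome)
    free_pairs = [p for p in slots
                  if p[0] not in used_genes and p[1] not in used_genes]
    rng.shuffle(free_pairs)

    def pop_pair() -> tuple[str, str]:
        while free_pairs:
            a, c = free_pairs.pop()
            if a not in used_genes and c not in used_genes:
                used_genes.update((a, c))
                return a, c
        raise RuntimeError("ran out of free homoeolog pairs")

    def pop_pair_tf_biased() -> tuple[str, str]:
        """Accept a candidate pair with probability proportional to
        ``feedback_tf_odds`` when its An member is a TF."""
        for _ in range(10 * len(free_pairs) + 10):
            if not free_pairs:
                break
            a, c = free_pairs[-1]
            if a in used_genes or c in used_genes:
                free_pairs.pop()
                continue
            w = cfg.feedback_tf_odds if genome[a].is_tf else 1.0
            if rng.random() < w / max(cfg.feedback_tf_odds, 1.0):
                free_pairs.pop()
                used_genes.update((a, c))
                return a, c
            # rotate
            free_pairs.insert(0, free_pairs.pop())
        return pop_pair()

    def plant_hgp(feedback: bool) -> None:
        a, c = pop_pair_tf_biased() if feedback else pop_pair()
        direction = str(rng.choice(["An_reg_Cn", "Cn_reg_An"]))
        reg_id, tgt_id = (a, c) if direction == "An_reg_Cn" else (c, a)
        reg = genome[reg_id]
        local_snp = None
        avoid = None
        if feedback:
            local_snp = _nearest_snp(gm, reg.chrom, reg.tss)
            avoid = int(blocks[local_snp])
            used_blocks.add(avoid)
        driver = _driver_snp(cfg, gm, blocks, reg.chrom, reg.tss, avoid,
                             cfg.hgp_window)
        if driver is None:
            warnings.warn(f"no driver SNP near {reg_id}; pair skipped")
            return
        used_blocks.add(int(blocks[driver]))
        flag = draw_ocr_flag()
        truth.ocr_flags[int(driver)] = flag
        if local_snp is not None:
            truth.ocr_flags[int(local_snp)] = draw_ocr_flag()
        truth.hgps.append(
            PlantedHGP(
                an_gene=a, cn_gene=c, direction=direction,
                driver_snp_idx=int(driver),
                driver_pos=int(gm.snps.at[driver, "pos"]),
                driver_chrom=reg.chrom,
                feedback=feedback,
                local_snp_idx=None if local_snp is None else int(local_snp),
                driver_in_ocr=flag,
            )
        )

    for _ in range(cfg.n_feedback_pairs):
        plant_hgp(feedback=True)
    for _ in range(cfg.n_nolocal_pairs):
        plant_hgp(feedback=False)

    for _ in range(cfg.n_biased_pairs):
        a, c = pop_pair()
        truth.biased_pairs.append(
            {"an_gene": a, "cn_gene": c, "shift": float(cfg.bias_shift)}
        )

    # ---- adjacent co-expressed pairs --------------------------------------
    patterns = ["both_open", "one_open", "both_closed"]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    candidates = []
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.ordinal)
        for g1, g2 in zip(chrom_genes, chrom_genes[1:]):
            candidates.append((g1, g2))
    rng.shuffle(candidates)
    planted_adj = 0
    for g1, g2 in candidates:
        if planted_adj >= cfg.n_adjacent_pairs:
            break
        if g1.gene_id in used_genes or g2.gene_id in used_genes:
            continue
        s1 = _nearest_snp(gm, g1.chrom, g1.tss)
        s2 = _nearest_snp(gm, g2.chrom, g2.tss, exclude={s1})
        if int(blocks[s1]) in used_blocks or int(blocks[s2]) in used_blocks:
            continue
        if blocks[s1] == blocks[s2]:
            continue
        pattern = patterns[planted_adj % 3]
        flag1, flag2 = {
            "both_open": (True, True),
            "one_open": (True, False),
            "both_closed": (False, False),
        }[pattern]
        used_genes.update((g1.gene_id, g2.gene_id))
        used_blocks.update((int(blocks[s1]), int(blocks[s2])))
        truth.ocr_flags[int(s1)] = flag1
        truth.ocr_flags[int(s2)] = flag2
        truth.adjacent_pairs.append(
            PlantedAdjacent(g1.gene_id, g2.gene_id, int(s1), int(s2), pattern)
        )
        planted_adj += 1
    if planted_adj < cfg.n_adjacent_pairs:
        warnings.warn("could not place all requested adjacent co-expressed pairs")

    # ---- build the two stage matrices -------------------------------------
    # homoeolog slots share a baseline so expression imbalance between the
    # subgenomes reflects planted shifts, not arbitrary per-gene means
    base_by_gene: dict[str, float] = {}
    base_mean = np.zeros(len(genes))
    for j, g in enumerate(genes):
        if g.chrom.startswith("C"):
            partner = g.gene_id.replace("Bna" + g.chrom,
                                        "Bna" + "A" + g.chrom[1:])
            if partner in base_by_gene:
                base_mean[j] = base_by_gene[partner]
                continue
        v = float(rng.normal(cfg.base_expr_mean, cfg.base_expr_sd))
        base_by_gene[g.gene_id] = v
        base_mean[j] = v

    def centered(j: int) -> np.ndarray:
        d = gm.dosages[:, j]
        return d - d.mean()

    def build_stage(stage: str) -> np.ndarray:
        L = np.tile(base_mean, (n, 1)) + rng.normal(0.0, cfg.noise_sd,
                                                    size=(n, len(genes)))
        for rec in truth.locals:
            if stage in rec.stages:
                L[:, col[rec.gene_id]] += rec.beta * centered(rec.snp_idx)
        for hs in truth.hotspots:
            jreg = col[hs.regulator_gene]
            L[:, jreg] += cfg.regulator_cis_effect * centered(hs.cis_snp_idx)
            reg_dev = L[:, jreg] - L[:, jreg].mean()
            for t, c in zip(hs.targets, hs.coefs):
                L[:, col[t]] += c * reg_dev
        for hgp in truth.hgps:
            reg_id, tgt_id = (
                (hgp.an_gene, hgp.cn_gene)
                if hgp.direction == "An_reg_Cn"
                else (hgp.cn_gene, hgp.an_gene)
            )
            jreg, jtgt = col[reg_id], col[tgt_id]
            if hgp.local_snp_idx is not None:
                L[:, jreg] += cfg.local_effect * centered(hgp.local_snp_idx)
            delta = cfg.distant_effect
            if hgp.driver_in_ocr:
                delta *= cfg.ocr_effect_boost
            L[:, jtgt] += delta * centered(hgp.driver_snp_idx)
            if hgp.feedback:
                reg_dev = L[:, jreg] - L[:, jreg].mean()
                L[:, jtgt] += cfg.feedback_strength * reg_dev
        for bp in truth.biased_pairs:
            L[:, col[bp["an_gene"]]] += bp["shift"]
        for adj in truth.adjacent_pairs:
            ja, jb = col[adj.gene_a], col[adj.gene_b]
            boost_a = cfg.ocr_effect_boost if truth.ocr_flags[adj.snp_a] else 1.0
            boost_b = cfg.ocr_effect_boost if truth.ocr_flags[adj.snp_b] else 1.0
            L[:, ja] += cfg.local_effect * boost_a * centered(adj.snp_a)
            L[:, jb] += cfg.local_effect * boost_b * centered(adj.snp_b)
            shared = rng.normal(0.0, cfg.shared_factor_sd, size=n)
            L[:, ja] += shared
            L[:, jb] += shared
            if adj.pattern in ("both_open", "both_closed"):
                # same-state coupling scales with the in-OCR effect boost so
                # the coupled share of variance is comparable across strata
                sd = cfg.state_coupling_sd * (cfg.ocr_effect_boost
                                              if adj.pattern == "both_open" else 1.0)
                extra = rng.normal(0.0, sd, size=n)
                L[:, ja] += extra
                L[:, jb] += extra
        return L

    accs = [f"acc{i:04d}" for i in range(n)]
    L1 = build_stage(STAGE1)
    L2 = build_stage(STAGE2)
    expr1 = ExpressionMatrix(accs, gene_ids, np.power(2.0, L1), stage=STAGE1)
    expr2 = ExpressionMatrix(accs, gene_ids, np.power(2.0, L2), stage=STAGE2)
    return expr1, expr2, truth


# ---------------------------------------------------------------------------
# OCRs, trait, similarity
# ---------------------------------------------------------------------------

def simulate_ocrs(
    cfg: SimConfig, genome: Genome, gm: GenotypeMatrix, truth: GroundTruth,
    rng: np.random.Generator,
) -> IntervalSet:
    """Open-chromatin intervals covering ~``ocr_fraction`` of the genome.

    The open state is treated as a property of the planted regulatory
    locus: a causal SNP flagged in-OCR receives a peak, and so do its LD
    block-mates (unless themselves flagged closed), so whichever block-mate
    ends up as the detected lead carries the planted chromatin state.
    Flagged-out causal SNPs are excluded from every peak.
    """
    lo_len, hi_len = cfg.ocr_len_range
    lengths = genome.chrom_lengths
    blocks = _snp_blocks(cfg, gm)
    rows: list[tuple[str, int, int]] = []
    excluded: dict[str, np.ndarray] = {}
    ex_rows: dict[str, list[int]] = {}
    cover: set[int] = set()
    for idx, flag in sorted(truth.ocr_flags.items()):
        if flag:
            cover.add(idx)
            for mate in np.flatnonzero(blocks == blocks[idx]):
                if truth.ocr_flags.get(int(mate), True):
                    cover.add(int(mate))
        else:
            chrom = str(gm.snps.at[idx, "chrom"])
            ex_rows.setdefault(chrom, []).append(int(gm.snps.at[idx, "pos"]))
    for idx in sorted(cover):
        chrom = str(gm.snps.at[idx, "chrom"])
        pos = int(gm.snps.at[idx, "pos"])
        length = int(rng.integers(lo_len, hi_len))
        off = int(rng.integers(50, max(51, length - 50)))
        start = max(0, pos - off)
        end = min(lengths[chrom], start + length)
        rows.append((chrom, start, end))
    for chrom, ps in ex_rows.items():
        excluded[chrom] = np.array(sorted(ps))

    covered = sum(e - s for _, s, e in rows)
    target = cfg.ocr_fraction * genome.total_length
    mean_len = (lo_len + hi_len) / 2
    n_bg = max(0, int(round((target - covered) / mean_len)))
    cum = np.cumsum([lengths[c] for c in genome.chromosomes["name"]])
    names = list(genome.chromosomes["name"])
    placed = 0
    attempts = 0
    while placed < n_bg and attempts < 50 * n_bg + 100:
        attempts += 1
        x = int(rng.integers(0, genome.total_length))
        ci = int(np.searchsorted(cum, x, side="right"))
        chrom = names[ci]
        offset = x - (0 if ci == 0 else int(cum[ci - 1]))
        length = int(rng.integers(lo_len, hi_len))
        start = min(offset, lengths[chrom] - length - 1)
        end = start + length
        ex = excluded.get(chrom)
        if ex is not None:
            i = np.searchsorted(ex, start)
            if i < len(ex) and ex[i] < end:
                continue
        rows.append((chrom, start, end))
        placed += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(df).merged()


def simulate_trait(
    cfg: SimConfig, expr: ExpressionMatrix, truth: GroundTruth,
    rng: np.random.Generator,
) -> pd.Series:
    """Quantitative trait = weighted causal-gene log expression + noise."""
    y = np.zeros(len(expr.accessions))
    for rec in truth.trait_causal:
        y += rec["weight"] * expr.gene_vector(rec["gene_id"])
    y += rng.normal(0.0, cfg.trait_noise_sd, size=len(y))
    return pd.Series(y, index=expr.accessions, name="trait")


def simulate_similarity(
    genome: Genome, rng: np.random.Generator, n_decoys: int = 3
) -> pd.DataFrame:
    """Cross-subgenome similarity scores: high on true homoeolog slots, a
    few low-scoring decoy hits elsewhere, to exercise reciprocal-best-hit
    pairing honestly."""
    pairs = homoeolog_slots(genome)
    cn_ids = [g.gene_id for g in genome.genes if g.chrom.startswith("C")]
    rows = []
    for a, c in pairs:
        rows.append((a, c, float(rng.uniform(0.85, 0.999))))
        decoys = rng.choice(len(cn_ids), size=n_decoys, replace=False)
        for d in decoys:
            if cn_ids[int(d)] != c:
                rows.append((a, cn_ids[int(d)], float(rng.uniform(0.1, 0.6))))
    return pd.DataFrame(rows, columns=["an_gene", "cn_gene", "score"])


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    cfg: SimConfig
    genome: Genome
    genotypes: GenotypeMatrix
    expr1: ExpressionMatrix
    expr2: ExpressionMatrix
    truth: GroundTruth
    ocrs: IntervalSet
    trait: pd.Series
    similarity: pd.DataFrame


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate a full synthetic study from a single seeded RNG stream."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = simulate_genome(cfg, rng)
    gm = simulate_genotypes(cfg, genome, rng)
    expr1, expr2, truth = simulate_expression(cfg, genome, gm, rng)
    ocrs = simulate_ocrs(cfg, genome, gm, truth, rng)
    trait = simulate_trait(cfg, expr1, truth, rng)
    similarity = simulate_similarity(genome, rng)
    return SimulatedStudy(cfg, genome, gm, expr1, expr2, truth, ocrs, trait,
                          similarity)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write the study to disk in standard exchange formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_gff3(study.genome, out / "genome.gff3")
    write_vcf(study.genotypes, out / "genotypes.vcf", study.genome)
    write_expression_tsv(study.expr1, out / "expr_20.tsv")
    write_expression_tsv(study.expr2, out / "expr_40.tsv")
    write_bed(study.ocrs, out / "ocr.bed")
    write_trait_tsv(study.trait, out / "trait.tsv")
    write_similarity_tsv(study.similarity, out / "similarity.tsv")
    write_tf_list(study.genome.tf_ids(), out / "tf_list.txt")
    study.truth.to_json(out / "truth.json")
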