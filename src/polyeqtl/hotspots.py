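"""Distant-eQTL hotspot detection by sliding-window permutation testing.

Distant-eQTL lead SNPs are counted in 1-Mb windows stepped every 100 kb.
The null distribution of the genome-wide maximum window count is obtained
by repeatedly scattering the same number of leads uniformly over the
genome; windows whose count clears the (1 - alpha) tail of that null are
hotspots. Overlapping or abutting called windows merge into one hotspot
carrying the distinct leads and regulated genes inside the merged interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import EqtlRecord
from .formats_io import Genome

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 100_000


@dataclass
class Hotspot:
    chrom: str
    start: int
    end: int
    eqtl_count: int
    empirical_p: float
    regulated_genes: frozenset[str] = frozenset()
    stage: str = ""
    overlap_status: str | None = None  # special | partial | overlap

    def length(self) -> int:
        return self.end - self.start


def genome_windows(genome: Genome, window: int = DEFAULT_WINDOW,
                   step: int = DEFAULT_STEP) -> pd.DataFrame:
    """All sliding windows per chromosome (final partial window included)."""
    rows = []
    for _, crow in genome.chromosomes.iterrows():
        chrom, length = crow["name"], int(crow["length"])
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + window, length)))
            if start + window >= length:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_counts(
    leads: pd.DataFrame,
    genome: Genome,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Lead-SNP count per sliding window.

    ``leads`` needs columns chrom, pos (0-based). Count of window [s, e) is
    the number of leads with s <= pos < e.
    """
    win = genome_windows(genome, window, step)
    counts = np.zeros(len(win), dtype=int)
    for chrom, sub in leads.groupby("chrom", sort=True):
        pos = np.sort(sub["pos"].to_numpy(int))
        mask = (win["chrom"] == chrom).to_numpy()
        s = win.loc[mask, "start"].to_numpy(int)
        e = win.loc[mask, "end"].to_numpy(int)
        counts[mask] = np.searchsorted(pos, e, side="left") - np.searchsorted(
            pos, s, side="left"
        )
    out = win.copy()
    out["count"] = counts
    return out


def permute_max_null(
    n_leads: int,
    genome: Genome,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null maxima: scatter ``n_leads`` uniformly over the concatenated
    genome, take the genome-wide maximum window count, repeat ``n_perm``
    times."""
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable hotspot threshold")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lengths = genome.chromosomes["length"].to_numpy(int)
    names = list(genome.chromosomes["name"])
    cum = np.cumsum(lengths)
    total = int(cum[-1])
    if total <= window and len(lengths) == 1:
        # single chromosome not longer than one window: every lead is in it
        return np.full(n_perm, n_leads, dtype=int)
    win = genome_windows(genome, window, step)
    win_by_chrom = {
        c: (sub["start"].to_numpy(int), sub["end"].to_numpy(int), sub.index.to_numpy())
        for c, sub in win.groupby("chrom", sort=True)
    }
    maxima = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        x = rng.integers(0, total, size=n_leads)
        ci = np.searchsorted(cum, x, side="right")
        best = 0
        for k, chrom in enumerate(names):
            pos = x[ci == k] - (0 if k == 0 else cum[k - 1])
            if len(pos) == 0:
                continue
            pos = np.sort(pos)
            s, e, _ = win_by_chrom[chrom]
            c = np.searchsorted(pos, e, side="left") - np.searchsorted(
                pos, s, side="left"
            )
            if len(c):
                best = max(best, int(c.max()))
        maxima[b] = best
    return maxima


def hotspot_threshold(null_maxima: np.ndarray, alpha: float = 0.01) -> int:
    """Smallest integer count c with fraction(null maxima >= c) < alpha."""
    null_maxima = np.asarray(null_maxima)
    c = 0
    while np.mean(null_maxima >= c) >= alpha:
        c += 1
    return c


def call_hotspots(
    counts: pd.DataFrame,
    null_maxima: np.ndarray,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Windows whose count clears the permutation threshold.

    ``empirical_p`` of a window is the fraction of null genome-wide maxima
    at or above its count.
    """
    c = hotspot_threshold(null_maxima, alpha)
    called = counts[counts["count"] >= c].copy()
    null_sorted = np.sort(np.asarray(null_maxima))
    n = len(null_sorted)
    called["empirical_p"] = [
        float((n - np.searchsorted(null_sorted, cnt, side="left")) / n)
        for cnt in called["count"]
    ]
    called.attrs["threshold"] = c
    return called.reset_index(drop=True)


def merge_hotspots(
    called: pd.DataFrame,
    leads: pd.DataFrame | None = None,
    merge_gap: int = 0,
    stage: str = "",
) -> list[Hotspot]:
    """Union overlapping/abutting called windows into hotspots.

    ``leads`` (columns chrom, pos, gene_id) provides the distinct lead count
    and the regulated-gene set of each merged interval.
    """
    hotspots: list[Hotspot] = []
    if len(called) == 0:
        return hotspots
    for chrom, sub in called.sort_values(["chrom", "start"]).groupby("chrom",
                                                                     sort=True):
        cur = None
        for _, row in sub.iterrows():
            s, e, p = int(row["start"]), int(row["end"]), float(row["empirical_p"])
            if cur is None:
                cur = [s, e, p]
            elif s <= cur[1] + merge_gap:
                cur[1] = max(cur[1], e)
                cur[2] = min(cur[2], p)
            else:
                hotspots.append(_finish(chrom, cur, leads, stage))
                cur = [s, e, p]
        if cur is not None:
            hotspots.append(_finish(chrom, cur, leads, stage))
    return hotspots


def _finish(chrom: str, cur: list, leads: pd.DataFrame | None,
            stage: str) -> Hotspot:
    s, e, p = int(cur[0]), int(cur[1]), float(cur[2])
    count = 0
    genes: frozenset[str] = frozenset()
    if leads is not None and len(leads):
        inside = leads[(leads["chrom"] == chrom)
                       & (leads["pos"] >= s) & (leads["pos"] < e)]
        # one eQTL = one (gene, lead) pair; identical rows are duplicates
        if "gene_id" in inside.columns:
            count = len(inside.drop_duplicates(["pos", "gene_id"]))
        else:
            count = int(inside["pos"].nunique())
        if "gene_id" in inside.columns:
            genes = frozenset(inside["gene_id"])
    return Hotspot(chrom, s, e, count, p, genes, stage)


def leads_frame(records: list[EqtlRecord],
                category: str = "distant") -> pd.DataFrame:
    """chrom/pos/gene_id of eQTL leads in the given category."""
    rows = [
        (r.chrom, r.pos, r.gene_id)
        for r in records
        if category is None or r.category == category
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id"])


def detect_hotspots(
    records: list[EqtlRecord],
    genome: Genome,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
    stage: str = "",
) -> tuple[list[Hotspot], pd.DataFrame, np.ndarray]:
    """Full hotspot pipeline for one stage's eQTL records."""
    leads = leads_frame(records, "distant")
    counts = window_counts(leads, genome, window, step)
    null = permute_max_null(len(leads), genome, window, step, n_perm, seed)
    called = call_hotspots(counts, null, alpha)
    merged = merge_hotspots(called, leads, stage=stage)
    return merged, counts, null


# ---------------------------------------------------------------------------
# Stage comparison and TWAS enrichment
# ---------------------------------------------------------------------------

def _overlap_frac(a: Hotspot, b: Hotspot) -> tuple[float, float]:
    if a.chrom != b.chrom:
        return 0.0, 0.0
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return ov / a.length(), ov / b.length()


def stage_overlap_hotspots(
    h1: list[Hotspot], h2: list[Hotspot], overlap_frac: float = 0.9
) -> None:
    """Label each hotspot special / partial / overlap against the other
    stage. "overlap" requires reciprocal coverage >= ``overlap_frac``;
    any lesser overlap is "partial"; none is "special"."""
    for mine, theirs in ((h1, h2), (h2, h1)):
        for h in mine:
            status = "special"
            for other in theirs:
                fa, fb = _overlap_frac(h, other)
                if fa > 0:
                    if fa >= overlap_frac and fb >= overlap_frac:
                        status = "overlap"
                        break
                    status = "partial"
            h.overlap_status = status


def hotspot_gene_enrichment(
    hotspot_genes: set[str],
    twas_genes: set[str],
    universe: set[str],
) -> tuple[float, float]:
    """One-sided hypergeometric enrichment of TWAS genes among the genes
    regulated by a hotspot. Returns (odds ratio, upper-tail P)."""
    M = len(universe)
    K = len(twas_genes & universe)
    n = len(hotspot_genes & universe)
    k = len(hotspot_genes & twas_genes & universe)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    a, b = k, n - k
    c, d = K - k, M - K - (n - k)
    odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else 0.0)
    return float(odds), p


def enrich_all_hotspots(
    hotspots: list[Hotspot],
    twas_genes: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment per hotspot with BH correction."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for h in hotspots:
        odds, p = hotspot_gene_enrichment(set(h.regulated_genes), twas_genes,
                                          universe)
        rows.append((h.chrom, h.start, h.end, h.stage, len(h.regulated_genes),
                     odds, p))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "stage",
                                     "n_genes", "odds_ratio", "p"])
    if len(df):
        _, q, *_ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
    else:
        df["q"] = []
    return df


def hotspot_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [h.chrom for h in hotspots],
            "start": [h.start for h in hotspots],
            "end": [h.end for h in hotspots],
            "eqtl_count": [h.eqtl_count for h in hotspots],
            "empirical_p": [h.empirical_p for h in hotspots],
            "n_genes": [len(h.regulated_genes) for h in hotspots],
            "genes": [",".join(sorted(h.regulated_genes)) for h in hotspots],
            "stage": [h.stage for h in hotspots],
            "overlap_status": [h.overlap_status for h in hotspots],
        }
    )
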