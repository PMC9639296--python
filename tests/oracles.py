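"""Independent brute-force reference implementations.

These deliberately use explicit loops / exhaustive enumeration and share no
code with the package, so they can serve as oracles for the optimized
implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def maf_brute(dosages: np.ndarray) -> np.ndarray:
    out = []
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            out.append(0.0)
            continue
        f = col.sum() / (2 * len(col))
        out.append(min(f, 1 - f))
    return np.array(out)


def window_counts_brute(leads: pd.DataFrame, windows: pd.DataFrame) -> list[int]:
    counts = []
    for _, w in windows.iterrows():
        c = 0
        for _, l in leads.iterrows():
            if l["chrom"] == w["chrom"] and w["start"] <= l["pos"] < w["end"]:
                c += 1
        counts.append(c)
    return counts


def pearson_r2_brute(a: np.ndarray, b: np.ndarray) -> float:
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    if va == 0 or vb == 0:
        return 0.0
    return cov * cov / (va * vb)


def clump_brute(sig: pd.DataFrame, dosages: np.ndarray,
                r2_min: float) -> list[frozenset]:
    """Greedy absorption with explicit loops; returns member-index sets."""
    rows = sig.sort_values(["p", "r2", "pos"],
                           ascending=[True, False, True]).to_dict("records")
    groups = []
    while rows:
        lead = rows[0]
        members = {int(lead["snp"])}
        rest = []
        for r in rows[1:]:
            if pearson_r2_brute(dosages[:, int(lead["snp"])],
                                dosages[:, int(r["snp"])]) > r2_min:
                members.add(int(r["snp"]))
            else:
                rest.append(r)
        groups.append(frozenset(members))
        rows = rest
    return groups


def merge_intervals_brute(df: pd.DataFrame) -> pd.DataFrame:
    """Per-bp boolean-mask union (coordinates must be small)."""
    rows = []
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom]
        hi = int(sub["end"].max())
        mask = np.zeros(hi + 1, dtype=bool)
        for _, r in sub.iterrows():
            mask[int(r["start"]):int(r["end"])] = True
        start = None
        for i in range(hi + 1):
            if mask[i] and start is None:
                start = i
            elif not mask[i] and start is not None:
                rows.append((chrom, start, i))
                start = None
        if start is not None:
            rows.append((chrom, start, hi + 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def census_brute(local: set[str], genes_df: pd.DataFrame,
                 max_intervening: int) -> list[int]:
    counts = [0] * (max_intervening + 1)
    recs = genes_df[genes_df["gene_id"].isin(local)].to_dict("records")
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a["chrom"] != b["chrom"]:
                continue
            k = abs(a["ordinal"] - b["ordinal"]) - 1
            if 0 <= k <= max_intervening:
                counts[k] += 1
    return counts


def rbh_brute(sim: pd.DataFrame) -> set[tuple[str, str]]:
    pairs = set()
    an_genes = sim["an_gene"].unique()
    for a in an_genes:
        sub = sim[sim["an_gene"] == a]
        best = sub["score"].max()
        hits = sorted(sub.loc[sub["score"] == best, "cn_gene"].unique())
        if len(hits) != 1:
            continue
        c = hits[0]
        back = sim[sim["cn_gene"] == c]
        bbest = back["score"].max()
        bhits = sorted(back.loc[back["score"] == bbest, "an_gene"].unique())
        if len(bhits) == 1 and bhits[0] == a:
            pairs.add((a, c))
    return pairs


def hypergeom_tail_brute(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), by exact combinatorial sum."""
    total = 0.0
    denom = math.comb(M, n)
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(M - K, n - i) / denom
    return total


def aggregate_brute(topk_lists: list[list[str]]) -> dict[str, tuple[int, int]]:
    """tf -> (top_k_count, first_rank_count)."""
    out: dict[str, list[int]] = {}
    for lst in topk_lists:
        for i, tf in enumerate(lst):
            d = out.setdefault(tf, [0, 0])
            d[0] += 1
            if i == 0:
                d[1] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}


def max_null_independent(n_leads: int, chrom_lengths: dict[str, int],
                         window: int, step: int, n_perm: int,
                         seed: int) -> np.ndarray:
    """Second, independent implementation of the permutation-max null:
    multinomial split of leads over chromosomes, then per-window loops."""
    rng = np.random.default_rng(seed)
    names = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in names], float)
    probs = lens / lens.sum()
    maxima = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        ks = rng.multinomial(n_leads, probs)
        best = 0
        for name, k in zip(names, ks):
            if k == 0:
                continue
            pos = rng.uniform(0, chrom_lengths[name], size=k)
            start = 0
            length = chrom_lengths[name]
            while start < length:
                end = min(start + window, length)
                c = int(((pos >= start) & (pos < end)).sum())
                best = max(best, c)
                if start + window >= length:
                    break
                start += step
        maxima[b] = best
    return maxima
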