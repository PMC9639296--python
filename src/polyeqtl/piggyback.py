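"""Expression piggybacking of adjacent genes with local eQTLs.

Genes carrying local eQTLs sit next to each other more often than chance;
adjacent gene pairs also co-express, and more strongly when both members
carry a local eQTL whose lead SNPs share a chromatin state. This module
quantifies all three observations: an adjacency census against a
permutation null, pair classification (I: both local, II: one local,
III: neither; IV: a matched sample of non-adjacent both-local pairs) with
expression-correlation CDF comparisons, and chromatin-state stratification
of class-I pairs with Welch t-tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import ExpressionMatrix, Genome, IntervalSet


def adjacency_census(
    local_egenes: set[str], genome: Genome, max_intervening: int = 10
) -> pd.Series:
    """Counts of local-eGene pairs separated by exactly k intervening genes,
    for k = 0..max_intervening, on the same chromosome."""
    counts = np.zeros(max_intervening + 1, dtype=int)
    for chrom, sub in genome.genes_df.groupby("chrom", sort=True):
        ords = np.sort(
            sub.loc[sub["gene_id"].isin(local_egenes), "ordinal"].to_numpy(int)
        )
        for i in range(len(ords)):
            for j in range(i + 1, len(ords)):
                k = ords[j] - ords[i] - 1
                if k > max_intervening:
                    break
                counts[k] += 1
    return pd.Series(counts, index=pd.RangeIndex(max_intervening + 1, name="k"),
                     name="pairs")


def n_adjacent_slots(genome: Genome) -> int:
    return sum(
        max(0, len(sub) - 1) for _, sub in genome.genes_df.groupby("chrom")
    )


def adjacency_permutation(
    observed_adjacent: int,
    n_local: int,
    genome: Genome,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float]:
    """Permutation null for the adjacent (k = 0) pair count.

    Each permutation samples ``n_local`` genes uniformly without
    replacement and counts adjacent pairs among them. The empirical P is
    (1 + #null >= observed) / (n_perm + 1).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    df = genome.genes_df
    chrom_code = pd.factorize(df["chrom"])[0]
    key = chrom_code * (df["ordinal"].max() + 2) + df["ordinal"].to_numpy(int)
    key = np.sort(key)
    n_genes = len(df)
    null = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        pick = rng.choice(n_genes, size=n_local, replace=False)
        chosen = np.sort(key[pick])
        null[b] = int(np.sum(np.diff(chosen) == 1))
    p = float((1 + np.sum(null >= observed_adjacent)) / (n_perm + 1))
    return null, p


def classify_pairs(
    local_egenes: set[str],
    genome: Genome,
    rng: int | np.random.Generator = 0,
    n_class_iv: int | None = None,
) -> pd.DataFrame:
    """Label all adjacent pairs I/II/III and draw a class-IV sample.

    Class I: both genes carry a local eQTL; II: exactly one; III: neither.
    Class IV is a random sample of *non-adjacent* both-local pairs, sized
    to the class-I count by default, giving a comparable correlation CDF.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    for chrom, sub in genome.genes_df.groupby("chrom", sort=True):
        sub = sub.sort_values("ordinal")
        ids = sub["gene_id"].to_list()
        for a, b in zip(ids, ids[1:]):
            na = a in local_egenes
            nb = b in local_egenes
            cls = "I" if (na and nb) else ("II" if (na or nb) else "III")
            rows.append((a, b, 0, cls))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "intervening", "pair_class"])

    if n_class_iv is None:
        n_class_iv = int((df["pair_class"] == "I").sum())
    locs = sorted(local_egenes & {g.gene_id for g in genome.genes})
    adj = {frozenset((a, b)) for a, b in zip(df["gene_a"], df["gene_b"])}
    iv_rows = []
    if len(locs) >= 2 and n_class_iv > 0:
        seen = set()
        tries = 0
        while len(iv_rows) < n_class_iv and tries < 50 * n_class_iv + 100:
            tries += 1
            i, j = rng.choice(len(locs), size=2, replace=False)
            a, b = locs[int(i)], locs[int(j)]
            fs = frozenset((a, b))
            if fs in adj or fs in seen:
                continue
            seen.add(fs)
            ga, gb = genome[a], genome[b]
            interv = (abs(ga.ordinal - gb.ordinal) - 1
                      if ga.chrom == gb.chrom else -1)
            if interv == 0:
                continue
            iv_rows.append((a, b, interv, "IV"))
    if iv_rows:
        df = pd.concat(
            [df, pd.DataFrame(iv_rows, columns=df.columns)], ignore_index=True
        )
    return df


def pair_correlations(pairs: pd.DataFrame, expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation of log2(TPM+1) for each gene pair."""
    E = expr.log2p1()
    Ec = E - E.mean(axis=0)
    sd = Ec.std(axis=0)
    pcc = []
    n = E.shape[0]
    for _, row in pairs.iterrows():
        ja, jb = expr.col(row["gene_a"]), expr.col(row["gene_b"])
        if sd[ja] == 0 or sd[jb] == 0:
            pcc.append(np.nan)
        else:
            pcc.append(float((Ec[:, ja] @ Ec[:, jb]) / (n * sd[ja] * sd[jb])))
    out = pairs.copy()
    out["pcc"] = pcc
    return out


def class_ks_tests(pairs_with_pcc: pd.DataFrame) -> pd.DataFrame:
    """Two-sample KS tests between the correlation CDFs of every class pair."""
    rows = []
    classes = sorted(pairs_with_pcc["pair_class"].unique())
    for i, ca in enumerate(classes):
        for cb in classes[i + 1:]:
            xa = pairs_with_pcc.loc[pairs_with_pcc["pair_class"] == ca, "pcc"].dropna()
            xb = pairs_with_pcc.loc[pairs_with_pcc["pair_class"] == cb, "pcc"].dropna()
            if len(xa) < 2 or len(xb) < 2:
                continue
            ks = stats.ks_2samp(xa, xb)
            rows.append((ca, cb, float(xa.mean()), float(xb.mean()),
                         float(ks.statistic), float(ks.pvalue)))
    return pd.DataFrame(rows, columns=["class_a", "class_b", "mean_pcc_a",
                                       "mean_pcc_b", "ks_stat", "ks_p"])


def chromatin_strata(
    pairs_class_I: pd.DataFrame,
    lead_by_gene: dict[str, tuple[str, int]],
    ocr: IntervalSet,
) -> pd.DataFrame:
    """Stratify class-I pairs by OCR membership of the two lead SNPs.

    ``lead_by_gene`` maps each local eGene to its minimum-P lead (chrom,
    pos). Pairs whose leads are both inside OCRs are "both_open", exactly
    one inside "one_open", neither "both_closed"; a missing lead gives NA.
    """
    labels = []
    for _, row in pairs_class_I.iterrows():
        la = lead_by_gene.get(row["gene_a"])
        lb = lead_by_gene.get(row["gene_b"])
        if la is None or lb is None:
            labels.append("NA")
            continue
        ina, inb = ocr.contains([la[0], lb[0]], [la[1], lb[1]])
        n_open = int(ina) + int(inb)
        labels.append(["both_closed", "one_open", "both_open"][n_open])
    out = pairs_class_I.copy()
    out["chromatin_stratum"] = labels
    return out


def strata_tests(strata_df: pd.DataFrame) -> pd.DataFrame:
    """Welch t-tests of pair correlation between chromatin strata
    (same-state strata vs one_open)."""
    rows = []
    for a, b in (("both_open", "one_open"), ("both_closed", "one_open")):
        xa = strata_df.loc[strata_df["chromatin_stratum"] == a, "pcc"].dropna()
        xb = strata_df.loc[strata_df["chromatin_stratum"] == b, "pcc"].dropna()
        if len(xa) < 2 or len(xb) < 2:
            continue
        t = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append((a, b, float(xa.mean()), float(xb.mean()),
                     float(t.statistic), float(t.pvalue)))
    return pd.DataFrame(rows, columns=["stratum_a", "stratum_b", "mean_pcc_a",
                                       "mean_pcc_b", "t_stat", "t_p"])
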