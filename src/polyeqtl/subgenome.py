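"""Homoeolog pairing and cross-subgenome regulation analysis.

Homoeologous gene pairs (HGPs) between the An and Cn subgenomes are called
by reciprocal best hit (RBH) on a similarity score table. A gene X is said
to regulate its homoeolog Y when X's TSS lies within 150 kb of a
distant-eQTL lead of Y; pairs where exactly one direction holds are
asymmetrically regulated (aHGPs), the rest (neither or both directions)
symmetric (sHGPs). Expression propensity is the mean paired log2 difference
An - Cn across accessions (BH-adjusted paired t-test); feedback is probed
by comparing the cross-homoeolog expression correlation of aHGPs whose
regulating gene carries a local eQTL ("Local") against those without
("NoLocal"). A permutation test asks whether feedback pairs are enriched
for transcription factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assoc import EqtlRecord
from .formats_io import ExpressionMatrix, Genome

DEFAULT_HGP_WINDOW = 150_000


# ---------------------------------------------------------------------------
# Reciprocal best hit
# ---------------------------------------------------------------------------

def rbh_pairs(similarity: pd.DataFrame) -> list[tuple[str, str]]:
    """Reciprocal-best-hit pairs from a long-format similarity table.

    Keeps (a, c) iff c is a's unique best Cn hit and a is c's unique best
    An hit. A tie at either best hit (after lexicographic ordering the tied
    candidates compare equal in score) breaks reciprocity and drops the
    pair, matching a strict reading of "best hit".
    """
    best_ac: dict[str, tuple[str, float, bool]] = {}
    best_ca: dict[str, tuple[str, float, bool]] = {}
    for row in similarity.itertuples(index=False):
        a, c, s = row.an_gene, row.cn_gene, float(row.score)
        cur = best_ac.get(a)
        if cur is None or s > cur[1]:
            best_ac[a] = (c, s, False)
        elif s == cur[1] and c != cur[0]:
            best_ac[a] = (min(c, cur[0]), s, True)
        cur = best_ca.get(c)
        if cur is None or s > cur[1]:
            best_ca[c] = (a, s, False)
        elif s == cur[1] and a != cur[0]:
            best_ca[c] = (min(a, cur[0]), s, True)
    pairs = []
    for a, (c, _s, tied) in sorted(best_ac.items()):
        if tied:
            continue
        back = best_ca.get(c)
        if back is not None and back[0] == a and not back[2]:
            pairs.append((a, c))
    return pairs


# ---------------------------------------------------------------------------
# Regulation classes
# ---------------------------------------------------------------------------

def distant_leads_by_gene(records: list[EqtlRecord]) -> dict[str, list[tuple[str, int]]]:
    out: dict[str, list[tuple[str, int]]] = {}
    for r in records:
        if r.category == "distant":
            out.setdefault(r.gene_id, []).append((r.chrom, r.pos))
    return out


def _regulates(
    x_id: str, y_id: str, leads: dict[str, list[tuple[str, int]]],
    genome: Genome, window: int,
) -> bool:
    """True iff X's TSS is within +/-window bp of a distant-eQTL lead of Y
    (boundary inclusive)."""
    x = genome[x_id]
    for chrom, pos in leads.get(y_id, ()):
        if chrom == x.chrom and abs(pos - x.tss) <= window:
            return True
    return False


def regulation_class(
    an_gene: str,
    cn_gene: str,
    leads: dict[str, list[tuple[str, int]]],
    genome: Genome,
    window: int = DEFAULT_HGP_WINDOW,
) -> str:
    """One of An_reg_Cn / Cn_reg_An (aHGP) or none / mutual (sHGP)."""
    a_reg_c = _regulates(an_gene, cn_gene, leads, genome, window)
    c_reg_a = _regulates(cn_gene, an_gene, leads, genome, window)
    if a_reg_c and c_reg_a:
        return "mutual"
    if a_reg_c:
        return "An_reg_Cn"
    if c_reg_a:
        return "Cn_reg_An"
    return "none"


def classify_hgps(
    pairs: list[tuple[str, str]],
    records: list[EqtlRecord],
    genome: Genome,
    window: int = DEFAULT_HGP_WINDOW,
) -> pd.DataFrame:
    """Regulation class + local-eQTL flags for every RBH pair.

    ``local_flag_regulating`` / ``local_flag_regulated`` report whether the
    regulating / regulated gene of an aHGP carries a local eQTL.
    """
    leads = distant_leads_by_gene(records)
    local_genes = {r.gene_id for r in records if r.category == "local"}
    rows = []
    for a, c in pairs:
        cls = regulation_class(a, c, leads, genome, window)
        symmetric = cls in ("none", "mutual")
        if cls == "An_reg_Cn":
            reg, tgt = a, c
        elif cls == "Cn_reg_An":
            reg, tgt = c, a
        else:
            reg = tgt = None
        rows.append(
            {
                "an_gene": a,
                "cn_gene": c,
                "reg_class": cls,
                "symmetric": symmetric,
                "local_flag_regulating": reg in local_genes if reg else False,
                "local_flag_regulated": tgt in local_genes if tgt else False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression propensity
# ---------------------------------------------------------------------------

def expression_propensity(hgp_df: pd.DataFrame, expr: ExpressionMatrix,
                          fdr: float = 0.05) -> pd.DataFrame:
    """Per-pair expression propensity (log2fc, An minus Cn) with a paired
    two-sided t-test across accessions, BH-adjusted over all pairs.

    Positive log2fc means An-biased expression. ``imbalanced`` marks
    padj < ``fdr``.
    """
    E = expr.log2p1()
    log2fc, pvals = [], []
    for row in hgp_df.itertuples(index=False):
        xa = E[:, expr.col(row.an_gene)]
        xc = E[:, expr.col(row.cn_gene)]
        diff = xa - xc
        log2fc.append(float(diff.mean()))
        if np.allclose(diff, diff[0]):
            pvals.append(1.0 if abs(diff[0]) < 1e-12 else 0.0)
        else:
            pvals.append(float(stats.ttest_rel(xa, xc).pvalue))
    out = hgp_df.copy()
    out["log2fc"] = log2fc
    out["p_propensity"] = pvals
    if len(out):
        _, padj, *_ = multipletests(out["p_propensity"], method="fdr_bh")
        out["padj"] = padj
    else:
        out["padj"] = []
    out["imbalanced"] = out["padj"] < fdr
    return out


# ---------------------------------------------------------------------------
# Feedback
# ---------------------------------------------------------------------------

def cross_pcc(hgp_df: pd.DataFrame, expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between the two homoeologs of every pair."""
    E = expr.log2p1()
    Ec = E - E.mean(axis=0)
    sd = Ec.std(axis=0)
    n = E.shape[0]
    vals = []
    for row in hgp_df.itertuples(index=False):
        ja, jc = expr.col(row.an_gene), expr.col(row.cn_gene)
        if sd[ja] == 0 or sd[jc] == 0:
            vals.append(np.nan)
        else:
            vals.append(float((Ec[:, ja] @ Ec[:, jc]) / (n * sd[ja] * sd[jc])))
    out = hgp_df.copy()
    out["cross_pcc"] = vals
    return out


def feedback_analysis(
    hgp_df: pd.DataFrame,
    expr: ExpressionMatrix,
    condition_on: str = "regulating",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group aHGP cross-correlations by local-eQTL status and KS-test them.

    Groups: BG = all HGPs; Local = aHGPs whose regulating gene (or the
    regulated gene, with ``condition_on='regulated'``) carries a local
    eQTL; NoLocal = the remaining aHGPs. Returns (per-pair table with a
    ``feedback_group`` column, KS-test table).
    """
    flag_col = ("local_flag_regulating" if condition_on == "regulating"
                else "local_flag_regulated")
    df = cross_pcc(hgp_df, expr)
    asym = ~df["symmetric"]
    group = np.where(asym & df[flag_col], "Local",
                     np.where(asym, "NoLocal", "BG_only"))
    df["feedback_group"] = group
    groups = {
        "BG": df["cross_pcc"].dropna(),
        "Local": df.loc[df["feedback_group"] == "Local", "cross_pcc"].dropna(),
        "NoLocal": df.loc[df["feedback_group"] == "NoLocal", "cross_pcc"].dropna(),
    }
    rows = []
    for ga, gb in (("Local", "NoLocal"), ("Local", "BG"), ("NoLocal", "BG")):
        xa, xb = groups[ga], groups[gb]
        if len(xa) < 2 or len(xb) < 2:
            continue
        ks = stats.ks_2samp(xa, xb)
        rows.append((ga, gb, float(xa.mean()), float(xb.mean()),
                     float(ks.statistic), float(ks.pvalue)))
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_pcc_a",
                                        "mean_pcc_b", "ks_stat", "ks_p"])
    return df, tests


def tf_enrichment(
    pair_genes: set[str],
    genome: Genome,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[int, float]:
    """Permutation enrichment of TFs in a gene set.

    Observed = TF count in ``pair_genes``; null = TF counts in equal-sized
    uniform draws from all genes. Empirical P = fraction of null counts at
    or above the observed (with the +1 correction).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    all_ids = [g.gene_id for g in genome.genes]
    is_tf = np.array([genome[g].is_tf for g in all_ids])
    observed = sum(1 for g in pair_genes if g in genome and genome[g].is_tf)
    m = len(pair_genes)
    if m == 0 or not is_tf.any() or is_tf.all():
        return observed, 1.0
    null = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        pick = rng.choice(len(all_ids), size=m, replace=False)
        null[b] = int(is_tf[pick].sum())
    p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return observed, p
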