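"""Boosted-tree upstream-TF ranking for a target gene set.

For every target gene a gradient-boosted tree regressor predicts its
log2(TPM+1) from the expression of all transcription factors (the target
itself excluded from its own feature set). The per-TF total-gain
importances of each model yield the top-k candidate upstream TFs of that
target; counting how often each TF appears in the top-k (and at rank 1)
across the target set and sorting by those counts gives the final ranking.
The headline hyperparameters are n_estimators=1000, max_depth=3,
learning_rate=1e-4, reg_alpha=0, reg_lambda=1, all overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import ExpressionMatrix
from .hotspots import Hotspot

DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 1000,
    "max_depth": 3,
    "learning_rate": 0.0001,
    "reg_alpha": 0.0,
    "reg_lambda": 1.0,
}


@dataclass
class TfRanking:
    tf_id: str
    top_k_count: int
    first_rank_count: int
    rank: int


def train_target_model(
    expr: ExpressionMatrix,
    tf_list: list[str],
    target_gene: str,
    hyperparams: dict | None = None,
    seed: int = 0,
    min_samples: int = 50,
) -> pd.Series:
    """Per-TF total-gain importances of a boosted regressor for one target.

    Constant targets return all-zero importances with a warning. Runs
    single-threaded for reproducibility.
    """
    from xgboost import XGBRegressor

    if len(expr.accessions) < min_samples:
        raise ValueError(
            f"{len(expr.accessions)} samples < required {min_samples}"
        )
    feats = [t for t in tf_list if t != target_gene and t in expr._col]
    if not feats:
        raise ValueError("empty TF feature set")
    E = expr.log2p1()
    X = E[:, [expr.col(t) for t in feats]]
    y = E[:, expr.col(target_gene)]
    if y.std() == 0:
        warnings.warn(f"constant target expression for {target_gene}")
        return pd.Series(0.0, index=feats)
    params = dict(DEFAULT_HYPERPARAMS)
    params["tree_method"] = "exact"
    if hyperparams:
        params.update(hyperparams)
    model = XGBRegressor(
        **params,
        importance_type="total_gain",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    model.fit(X, y)
    booster = model.get_booster()
    scores = booster.get_score(importance_type="total_gain")
    imp = np.zeros(len(feats))
    for key, val in scores.items():
        imp[int(key[1:])] = val  # keys are "f<index>"
    return pd.Series(imp, index=feats)


def top_k_tfs(importances: pd.Series, k: int = 3) -> list[str]:
    """The k TFs with the highest importance; zero-importance TFs never
    qualify, ties break lexicographically by id."""
    nz = importances[importances > 0]
    ordered = sorted(nz.items(), key=lambda kv: (-kv[1], kv[0]))
    return [tf for tf, _ in ordered[:k]]


def aggregate_ranking(per_target_topk: list[list[str]]) -> list[TfRanking]:
    """Tally top-k and rank-1 occurrences across targets and rank TFs.

    Sort key: top_k_count desc, then first_rank_count desc, then id.
    Ties on both counts share a rank; ranks stay contiguous over tie
    groups (competition ranking).
    """
    topk: dict[str, int] = {}
    first: dict[str, int] = {}
    for lst in per_target_topk:
        for i, tf in enumerate(lst):
            topk[tf] = topk.get(tf, 0) + 1
            if i == 0:
                first[tf] = first.get(tf, 0) + 1
    entries = sorted(
        topk, key=lambda tf: (-topk[tf], -first.get(tf, 0), tf)
    )
    out: list[TfRanking] = []
    rank = 0
    prev_key = None
    for i, tf in enumerate(entries):
        key = (topk[tf], first.get(tf, 0))
        if key != prev_key:
            rank = i + 1
            prev_key = key
        out.append(TfRanking(tf, topk[tf], first.get(tf, 0), rank))
    return out


def rank_targets(
    expr: ExpressionMatrix,
    tf_list: list[str],
    target_genes: list[str],
    hyperparams: dict | None = None,
    k: int = 3,
    seed: int = 0,
) -> list[TfRanking]:
    """Fit one model per target and aggregate the top-k lists."""
    per_target = []
    for tgt in target_genes:
        imp = train_target_model(expr, tf_list, tgt, hyperparams, seed=seed)
        per_target.append(top_k_tfs(imp, k))
    return aggregate_ranking(per_target)


def rank_hotspot_tfs(
    expr: ExpressionMatrix,
    tf_list: list[str],
    target_genes: list[str],
    hotspot: Hotspot,
    genome,
    hyperparams: dict | None = None,
    k: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Full ranking annotated with hotspot membership of each TF.

    ``in_hotspot`` flags TFs whose gene body lies inside the hotspot
    interval; the headline candidate is the best-ranked in-hotspot TF.
    """
    ranking = rank_targets(expr, tf_list, target_genes, hyperparams, k, seed)
    rows = []
    for r in ranking:
        inside = False
        if r.tf_id in genome:
            g = genome[r.tf_id]
            inside = (g.chrom == hotspot.chrom and g.start >= hotspot.start
                      and g.end <= hotspot.end)
        rows.append((r.tf_id, r.top_k_count, r.first_rank_count, r.rank, inside))
    return pd.DataFrame(
        rows, columns=["tf_id", "top_k_count", "first_rank_count", "rank",
                       "in_hotspot"]
    )
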