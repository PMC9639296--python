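"""Per-gene association scan, LD clumping, local/distant classification, TWAS.

The scan regresses log2(TPM+1) on additive dosage, one SNP at a time
(ordinary least squares with optional genotype principal-component
covariates). Explained variance r2 is the squared Pearson correlation
between dosage and (covariate-residualized) expression; the p-value comes
from the t-test on the slope. Significant SNPs (default P <= 1e-6) are
greedily clumped: the smallest-P SNP becomes the lead and absorbs every
remaining significant SNP with LD r2 > 0.2 to it. An eQTL is *local* when
its lead lies within 500 kb of the gene body (boundary inclusive, same
chromosome) and *distant* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import ExpressionMatrix, GeneModel, Genome, GenotypeMatrix

P_FLOOR = 1e-300
DEFAULT_THRESHOLD = 1e-6
DEFAULT_LD_MIN = 0.2
DEFAULT_LOCAL_WINDOW = 500_000


@dataclass
class EqtlRecord:
    """One clumped eQTL: a lead SNP plus its absorbed member SNPs."""

    gene_id: str
    stage: str
    chrom: str
    pos: int                      # lead SNP position (0-based)
    lead_idx: int                 # column index into the genotype matrix
    member_idx: list[int]
    p: float
    r2: float
    beta: float
    category: str | None = None   # "local" | "distant"
    overlap_status: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.member_idx)


def shared_accessions(gm: GenotypeMatrix, expr: ExpressionMatrix) -> list[str]:
    have = set(expr.accessions)
    return [a for a in gm.accessions if a in have]


def genotype_pcs(gm: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal components of the (mean-imputed, centered) dosage
    matrix, for use as structure covariates."""
    d = gm.mean_imputed().dosages
    d = d - d.mean(axis=0)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    return u[:, :k] * s[:k]


def _residualize(y: np.ndarray, cov: np.ndarray | None) -> tuple[np.ndarray, int]:
    if cov is None or cov.size == 0:
        return y - y.mean(), 0
    X = np.column_stack([np.ones(len(y)), cov])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta, cov.shape[1]


def _corr_stats(D: np.ndarray, y: np.ndarray, n_cov: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized slope/r2/p of y on each column of D (complete data)."""
    n = len(y)
    Dc = D - D.mean(axis=0)
    sx = Dc.std(axis=0)
    sy = y.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Dc.T @ y) / (n * sx * sy)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - n_cov
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        beta = r * sy / np.where(sx > 0, sx, 1.0)
    t = np.where(np.abs(r) >= 1.0, np.inf * np.sign(r), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)
    return beta, r * r, p


def scan_gene(
    gm: GenotypeMatrix,
    expr: ExpressionMatrix,
    gene_id: str,
    covariates: np.ndarray | None = None,
    min_shared: int = 30,
) -> pd.DataFrame:
    """Association statistics of one gene against every SNP.

    Returns a DataFrame with columns gene_id, snp, chrom, pos, beta, r2, p
    (one row per SNP; ``snp`` is the column index in ``gm``). Accessions
    with missing dosage are dropped per SNP.
    """
    accs = shared_accessions(gm, expr)
    if len(accs) < min_shared:
        raise ValueError(
            f"only {len(accs)} shared accessions (< {min_shared}) for {gene_id}"
        )
    gm_s = gm.subset_accessions(accs)
    y = expr.subset_accessions(accs).gene_vector(gene_id)
    out = pd.DataFrame(
        {
            "gene_id": gene_id,
            "snp": np.arange(gm_s.n_snps),
            "chrom": gm_s.snps["chrom"].to_numpy(),
            "pos": gm_s.snps["pos"].to_numpy(int),
        }
    )
    if y.std() == 0:
        warnings.warn(f"zero-variance expression for {gene_id}; P set to 1")
        out["beta"], out["r2"], out["p"] = 0.0, 0.0, 1.0
        return out
    yr, n_cov = _residualize(y, covariates)
    D = gm_s.dosages
    if np.isnan(D).any():
        beta = np.zeros(gm_s.n_snps)
        r2 = np.zeros(gm_s.n_snps)
        p = np.ones(gm_s.n_snps)
        for j in range(gm_s.n_snps):
            ok = ~np.isnan(D[:, j])
            if ok.sum() < min_shared or D[ok, j].std() == 0:
                continue
            b, rr, pp = _corr_stats(D[ok, j][:, None], yr[ok] - yr[ok].mean(), n_cov)
            beta[j], r2[j], p[j] = b[0], rr[0], pp[0]
    else:
        beta, r2, p = _corr_stats(D, yr, n_cov)
    out["beta"], out["r2"], out["p"] = beta, r2, p
    return out


def scan_genes(
    gm: GenotypeMatrix,
    expr: ExpressionMatrix,
    gene_ids: list[str] | None = None,
    covariates: np.ndarray | None = None,
    threshold: float | None = None,
    min_shared: int = 30,
) -> pd.DataFrame:
    """Scan many genes at once (single matrix product over complete data).

    With ``threshold`` set, only rows at or below it are returned, which is
    the memory-friendly mode for genome-wide scans.
    """
    accs = shared_accessions(gm, expr)
    if len(accs) < min_shared:
        raise ValueError(f"only {len(accs)} shared accessions (< {min_shared})")
    gm_s = gm.subset_accessions(accs)
    expr_s = expr.subset_accessions(accs)
    if gene_ids is None:
        gene_ids = list(expr.gene_ids)
    if np.isnan(gm_s.dosages).any():
        frames = [
            scan_gene(gm, expr, g, covariates, min_shared) for g in gene_ids
        ]
        allstats = pd.concat(frames, ignore_index=True)
        if threshold is not None:
            allstats = allstats[allstats["p"] <= threshold].reset_index(drop=True)
        return allstats

    Y = expr_s.log2p1()[:, [expr_s.col(g) for g in gene_ids]]
    n = Y.shape[0]
    n_cov = 0
    if covariates is not None and covariates.size:
        X = np.column_stack([np.ones(n), covariates])
        H, *_ = np.linalg.lstsq(X, Y, rcond=None)
        Y = Y - X @ H
        n_cov = covariates.shape[1]
    Yc = Y - Y.mean(axis=0)
    sy = Yc.std(axis=0)
    D = gm_s.dosages
    Dc = D - D.mean(axis=0)
    sx = Dc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Yc.T @ Dc) / (n * np.outer(sy, sx))
    R = np.clip(np.nan_to_num(R, nan=0.0), -1.0, 1.0)
    df = n - 2 - n_cov
    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt(df) / np.sqrt(1.0 - R * R)
    T = np.where(np.abs(R) >= 1.0, np.inf * np.sign(R), T)
    P = np.clip(2.0 * stats.t.sf(np.abs(T), df), P_FLOOR, 1.0)
    zero_var = sy == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} genes with zero-variance expression")
        P[zero_var, :] = 1.0
        R[zero_var, :] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        B = R * (sy[:, None] / np.where(sx > 0, sx, 1.0)[None, :])

    snp_chrom = gm_s.snps["chrom"].to_numpy()
    snp_pos = gm_s.snps["pos"].to_numpy(int)
    frames = []
    for i, g in enumerate(gene_ids):
        if threshold is not None:
            keep = np.flatnonzero(P[i] <= threshold)
        else:
            keep = np.arange(len(snp_pos))
        if len(keep) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": g,
                    "snp": keep,
                    "chrom": snp_chrom[keep],
                    "pos": snp_pos[keep],
                    "beta": B[i, keep],
                    "r2": R[i, keep] ** 2,
                    "p": P[i, keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "snp", "chrom", "pos", "beta", "r2", "p"]
        )
    return pd.concat(frames, ignore_index=True)


def significant_snps(stats_df: pd.DataFrame,
                     threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Retain associations with P <= threshold."""
    return stats_df[stats_df["p"] <= threshold].reset_index(drop=True)


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Pairs with a missing value in either vector are dropped; a constant
    vector yields 0 with a warning.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        warnings.warn("constant dosage vector in LD computation; r2 set to 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    sig_stats: pd.DataFrame,
    gm: GenotypeMatrix,
    r2_min: float = DEFAULT_LD_MIN,
    stage: str = "",
) -> list[EqtlRecord]:
    """Greedy LD clumping of one gene's significant SNPs into eQTLs.

    Repeatedly takes the smallest-P SNP as lead (ties broken by larger r2,
    then lower coordinate) and absorbs every remaining SNP with LD r2 to
    the lead strictly greater than ``r2_min``. Every significant SNP ends
    up in exactly one record.
    """
    if len(sig_stats) == 0:
        return []
    gene_ids = sig_stats["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValueError("clump() expects statistics from a single gene")
    rows = sig_stats.sort_values(
        ["p", "r2", "pos"], ascending=[True, False, True]
    ).reset_index(drop=True)
    remaining = list(rows.index)
    records: list[EqtlRecord] = []
    while remaining:
        lead_row = rows.loc[remaining[0]]
        lead = int(lead_row["snp"])
        members = [lead]
        rest = []
        lead_dose = gm.dosages[:, lead]
        for i in remaining[1:]:
            snp = int(rows.at[i, "snp"])
            if ld_r2(lead_dose, gm.dosages[:, snp]) > r2_min:
                members.append(snp)
            else:
                rest.append(i)
        records.append(
            EqtlRecord(
                gene_id=str(lead_row["gene_id"]),
                stage=stage,
                chrom=str(lead_row["chrom"]),
                pos=int(lead_row["pos"]),
                lead_idx=lead,
                member_idx=sorted(members),
                p=float(lead_row["p"]),
                r2=float(lead_row["r2"]),
                beta=float(lead_row["beta"]),
            )
        )
        remaining = rest
    return records


def classify_eqtl(record: EqtlRecord, gene: GeneModel,
                  window: int = DEFAULT_LOCAL_WINDOW) -> str:
    """local iff the lead SNP is on the gene's chromosome within ``window``
    bp of the gene body, boundary inclusive."""
    if record.chrom != gene.chrom:
        return "distant"
    return "local" if gene.distance_to(record.pos) <= window else "distant"


def classify_all(records: list[EqtlRecord], genome: Genome,
                 window: int = DEFAULT_LOCAL_WINDOW) -> None:
    for rec in records:
        rec.category = classify_eqtl(rec, genome[rec.gene_id], window)


def call_eqtls(
    gm: GenotypeMatrix,
    expr: ExpressionMatrix,
    genome: Genome,
    threshold: float = DEFAULT_THRESHOLD,
    r2_min: float = DEFAULT_LD_MIN,
    window: int = DEFAULT_LOCAL_WINDOW,
    covariates: np.ndarray | None = None,
) -> list[EqtlRecord]:
    """Scan -> threshold -> clump -> classify for every expressed gene."""
    sig = scan_genes(gm, expr, covariates=covariates, threshold=threshold)
    records: list[EqtlRecord] = []
    for gene_id, sub in sig.groupby("gene_id", sort=True):
        records.extend(clump(sub, gm, r2_min=r2_min, stage=expr.stage))
    classify_all(records, genome, window)
    return records


def egene_summary(records: list[EqtlRecord]) -> pd.DataFrame:
    """Per-gene eQTL counts and local/distant tallies."""
    rows: dict[str, dict] = {}
    for rec in records:
        d = rows.setdefault(
            rec.gene_id, {"gene_id": rec.gene_id, "n_eqtl": 0,
                          "n_local": 0, "n_distant": 0}
        )
        d["n_eqtl"] += 1
        if rec.category == "local":
            d["n_local"] += 1
        elif rec.category == "distant":
            d["n_distant"] += 1
    return pd.DataFrame(list(rows.values())).reset_index(drop=True)


def _match(a: EqtlRecord, b: EqtlRecord, gm: GenotypeMatrix | None,
           match_window: int, r2_min: float) -> bool:
    if a.gene_id != b.gene_id or a.chrom != b.chrom:
        return False
    if abs(a.pos - b.pos) <= match_window:
        return True
    if gm is not None:
        return ld_r2(gm.dosages[:, a.lead_idx], gm.dosages[:, b.lead_idx]) > r2_min
    return False


def stage_overlap(
    records_s1: list[EqtlRecord],
    records_s2: list[EqtlRecord],
    gm: GenotypeMatrix | None = None,
    match_window: int = 100_000,
    r2_min: float = DEFAULT_LD_MIN,
) -> pd.DataFrame:
    """Label every eQTL as detected at both stages or one stage only.

    Two eQTLs of the same gene match across stages when their leads are
    within ``match_window`` bp or in LD (r2 > ``r2_min``).
    """
    by_gene2: dict[str, list[EqtlRecord]] = {}
    for rec in records_s2:
        by_gene2.setdefault(rec.gene_id, []).append(rec)
    rows = []
    matched2: set[int] = set()
    for rec in records_s1:
        partners = by_gene2.get(rec.gene_id, [])
        hit = None
        for other in partners:
            if _match(rec, other, gm, match_window, r2_min):
                hit = other
                break
        status = "both" if hit is not None else "s1_only"
        rec.overlap_status = status
        if hit is not None:
            matched2.add(id(hit))
        rows.append((rec.gene_id, rec.stage, rec.chrom, rec.pos, status))
    for rec in records_s2:
        status = "both" if id(rec) in matched2 else "s2_only"
        rec.overlap_status = status
        rows.append((rec.gene_id, rec.stage, rec.chrom, rec.pos, status))
    return pd.DataFrame(rows, columns=["gene_id", "stage", "chrom", "pos", "status"])


def twas(
    expr: ExpressionMatrix,
    trait: pd.Series,
    fdr: float = 0.05,
    min_shared: int = 30,
) -> pd.DataFrame:
    """Per-gene OLS of the trait on log2(TPM+1) with BH FDR control.

    Returns gene_id, beta, p, q, significant (q <= ``fdr``).
    """
    accs = [a for a in expr.accessions if a in trait.index]
    if len(accs) < min_shared:
        raise ValueError(f"only {len(accs)} shared accessions (< {min_shared})")
    E = expr.subset_accessions(accs).log2p1()
    y = trait.loc[accs].to_numpy(float)
    yc = y - y.mean()
    sy = yc.std()
    n = len(y)
    Ec = E - E.mean(axis=0)
    se = Ec.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ec.T @ yc) / (n * se * sy)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1 - r * r)
        beta = r * sy / np.where(se > 0, se, 1.0)
    t = np.where(np.abs(r) >= 1.0, np.inf * np.sign(r), t)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR, 1.0)
    _, q, *_ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "beta": beta,
            "p": p,
            "q": q,
            "significant": q <= fdr,
        }
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def eqtl_table(records: list[EqtlRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "stage": [r.stage for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "lead_idx": [r.lead_idx for r in records],
            "n_members": [r.n_members for r in records],
            "members": [",".join(map(str, r.member_idx)) for r in records],
            "p": [r.p for r in records],
            "r2": [r.r2 for r in records],
            "beta": [r.beta for r in records],
            "category": [r.category for r in records],
            "overlap_status": [r.overlap_status for r in records],
        }
    )


def records_from_table(df: pd.DataFrame) -> list[EqtlRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            EqtlRecord(
                gene_id=str(row["gene_id"]),
                stage=str(row["stage"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                lead_idx=int(row["lead_idx"]),
                member_idx=[int(x) for x in str(row["members"]).split(",")],
                p=float(row["p"]),
                r2=float(row["r2"]),
                beta=float(row["beta"]),
                category=None if pd.isna(row.get("category")) else str(row["category"]),
                overlap_status=(
                    None if pd.isna(row.get("overlap_status"))
                    else str(row["overlap_status"])
                ),
            )
        )
    return records
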