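"""Gene-signature scoring, metabolic enrichment scan and composition tables.

Per-cell signature scores follow the bin-matched control-gene scheme used
throughout single-cell work: a cell's score for a gene set is its mean
log-normalised expression over the set minus the mean over control genes
drawn, for each set gene, from the same average-expression bin.  Scores of
random sets are therefore centred on zero regardless of cell depth or
overall expression level.

The metabolic enrichment scan scores a panel of pathways (21 metabolic
gene sets in the bundled demo collection) on keratinocytes, contrasts
stress keratinocytes against the remaining keratinocytes (difference of
mean scores, two-sided Wilcoxon rank-sum p), and correlates each pathway's
per-cell score with the stress-signature score.  Pathways coupled to the
stress state land in the (+delta, +r) or (-delta, -r) quadrants.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignatureScoreSet",
    "normalize_expression",
    "score_signature",
    "wilcoxon_rank_sum",
    "compare_scores",
    "metabolic_enrichment_scan",
    "diff_expr_in_universe",
    "composition_table",
]


@dataclass
class SignatureScoreSet:
    """Per-cell scores for one gene set."""

    set_name: str
    per_cell_score: np.ndarray
    genes_used: list[str]
    control_genes_used: list[str]
    n_bins: int
    n_ctrl_per_gene: int
    seed: int


def normalize_expression(
    counts: np.ndarray, scale: float = 1e4
) -> tuple[np.ndarray, np.ndarray]:
    """Library-size normalisation to ``scale`` counts/cell, then log1p.

    Returns ``(normalized, kept)`` where ``kept`` is a boolean mask of
    cells with non-zero library size (zero cells are dropped with a
    warning).  Deterministic; doubling a cell's counts leaves its
    normalised vector unchanged.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be cells x genes")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=1)
    kept = lib > 0
    n_dropped = int((~kept).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-count cells")
    X = counts[kept].astype(float)
    X = np.log1p(X * (scale / lib[kept][:, None]))
    return X, kept


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size rank bins of genes by average expression."""
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(len(mean_expr), dtype=int)
    bins[order] = np.arange(len(mean_expr)) * n_bins // len(mean_expr)
    return bins


def score_signature(
    norm_expr: np.ndarray,
    gene_names: Sequence[str],
    gene_set: Sequence[str],
    set_name: str = "signature",
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> SignatureScoreSet:
    """Bin-matched control signature score per cell.

    For each set gene, ``n_ctrl`` control genes are sampled (with
    replacement if the bin is small, excluding set genes) from the gene's
    average-expression bin; the score is the mean expression of the set
    minus the mean expression of the pooled controls.  With ``n_ctrl=0``
    the plain mean expression of the set is returned (documented fallback).
    Genes absent from the matrix are dropped with a warning; an entirely
    absent set is an error.
    """
    X = np.asarray(norm_expr)
    names = list(gene_names)
    idx_of = {g: i for i, g in enumerate(names)}
    present = [g for g in gene_set if g in idx_of]
    missing = [g for g in gene_set if g not in idx_of]
    if not present:
        raise ValueError(
            f"gene set {set_name!r} entirely absent from matrix: {missing[:10]}"
        )
    if missing:
        warnings.warn(f"{set_name}: dropped {len(missing)} absent genes")
    set_idx = np.array([idx_of[g] for g in present])
    set_score = X[:, set_idx].mean(axis=1)
    if n_ctrl == 0:
        return SignatureScoreSet(
            set_name=set_name,
            per_cell_score=set_score,
            genes_used=present,
            control_genes_used=[],
            n_bins=n_bins,
            n_ctrl_per_gene=0,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    mean_expr = X.mean(axis=0)
    bins = _expression_bins(mean_expr, n_bins)
    in_set = np.zeros(len(names), dtype=bool)
    in_set[set_idx] = True
    ctrl_idx: list[int] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if len(pool) == 0:
            continue
        take = rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False)
        ctrl_idx.extend(take.tolist())
    if not ctrl_idx:
        raise ValueError("no control genes available outside the set")
    ctrl_idx = np.asarray(sorted(set(ctrl_idx)))
    ctrl_score = X[:, ctrl_idx].mean(axis=1)
    return SignatureScoreSet(
        set_name=set_name,
        per_cell_score=set_score - ctrl_score,
        genes_used=present,
        control_genes_used=[names[i] for i in ctrl_idx],
        n_bins=n_bins,
        n_ctrl_per_gene=n_ctrl,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_u_sf(u_obs: float, n: int, m: int) -> float:
    """P(U >= u_obs) by full enumeration of rank assignments (no ties)."""
    total = comb(n + m, n)
    count = 0
    for combo in itertools.combinations(range(n + m), n):
        # U for group x occupying these pooled ranks
        u = sum(combo) - n * (n - 1) // 2
        if u >= u_obs:
            count += 1
    return count / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` with ``U`` the Mann-Whitney statistic of ``x``
    (number of (x, y) pairs with x > y, ties counting half).  The p-value
    is by exact enumeration when ``n + m <= 12`` and the pooled sample has
    no ties, and by the normal approximation with tie and continuity
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n].sum()
    u = r1 - n * (n + 1) / 2.0

    has_ties = len(np.unique(pooled)) < n + m
    if n + m <= 12 and not has_ties:
        hi = _exact_u_sf(u, n, m)
        lo = _exact_u_sf(n * m - u, n, m)  # P(U <= u) by symmetry
        p = min(1.0, 2.0 * min(hi, lo))
        return float(u), float(p)

    mean_u = n * m / 2.0
    nt = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (nt * (nt - 1.0))
    var_u = n * m / 12.0 * ((nt + 1.0) - tie_term)
    if var_u <= 0:
        return float(u), 1.0
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return float(u), p


def _rank_sum_genewise(
    X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> np.ndarray:
    """Vectorised normal-approximation rank-sum p per column (gene)."""
    sub = X[mask_a | mask_b]
    a_rows = mask_a[mask_a | mask_b]
    n, m = int(mask_a.sum()), int(mask_b.sum())
    nt = n + m
    ranks = stats.rankdata(sub, axis=0)
    r1 = ranks[a_rows].sum(axis=0)
    u = r1 - n * (n + 1) / 2.0
    # tie correction per gene
    tie_term = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(sub[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts) / (nt * (nt - 1.0))
    var_u = n * m / 12.0 * ((nt + 1.0) - tie_term)
    z = np.zeros(X.shape[1])
    pos = var_u > 0
    z[pos] = np.maximum(np.abs(u[pos] - n * m / 2.0) - 0.5, 0.0) / np.sqrt(var_u[pos])
    p = np.where(pos, 2.0 * stats.norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


def compare_scores(
    scores: np.ndarray,
    group_labels: Sequence[str],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Pairwise mean differences and Wilcoxon p for labelled score groups."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must align")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if pairs is None:
        pairs = list(itertools.combinations(uniq, 2))
    rows = []
    for a, b in pairs:
        for g in (a, b):
            if g not in uniq:
                raise ValueError(f"unknown group label {g!r}")
        xa = scores[labels == a]
        xb = scores[labels == b]
        u, p = wilcoxon_rank_sum(xa, xb)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "delta_mean": float(xa.mean() - xb.mean()),
                "u_statistic": u,
                "p_value": p,
                "n_a": len(xa),
                "n_b": len(xb),
            }
        )
    return pd.DataFrame(rows)


def metabolic_enrichment_scan(
    norm_expr: np.ndarray,
    gene_names: Sequence[str],
    pathway_sets: Mapping[str, Sequence[str]],
    stress_markers: Sequence[str],
    keratinocyte_mask: np.ndarray,
    stress_mask: np.ndarray,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Scan pathways for coupling to the stress-keratinocyte signature.

    For each pathway: per-cell signature scores on keratinocytes,
    ``delta_score`` = mean score (stress keratinocytes) - mean score (other
    keratinocytes), ``stress_corr`` = Pearson r between the pathway score
    and the stress-marker score across all keratinocytes, and a two-sided
    Wilcoxon rank-sum p for stress vs other.  Rows are sorted by
    ``|delta_score|`` descending.
    """
    keratinocyte_mask = np.asarray(keratinocyte_mask, dtype=bool)
    stress_mask = np.asarray(stress_mask, dtype=bool)
    if stress_mask.shape != keratinocyte_mask.shape:
        raise ValueError("masks must align")
    if np.any(stress_mask & ~keratinocyte_mask):
        raise ValueError("stress_mask must be a subset of keratinocyte_mask")
    if not stress_mask.any():
        raise ValueError("empty stress group")
    X = np.asarray(norm_expr)[keratinocyte_mask]
    stress_in_kc = stress_mask[keratinocyte_mask]

    stress_score = score_signature(
        X, gene_names, stress_markers, "stress_markers", n_bins, n_ctrl, seed
    ).per_cell_score
    rows = []
    for i, (name, genes) in enumerate(pathway_sets.items()):
        s = score_signature(
            X, gene_names, genes, name, n_bins, n_ctrl, seed + i + 1
        ).per_cell_score
        delta = float(s[stress_in_kc].mean() - s[~stress_in_kc].mean())
        r = float(np.corrcoef(s, stress_score)[0, 1])
        _, p = wilcoxon_rank_sum(s[stress_in_kc], s[~stress_in_kc])
        rows.append(
            {
                "pathway_name": name,
                "delta_score": delta,
                "stress_corr": r,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.reindex(df["delta_score"].abs().sort_values(ascending=False).index)
        .reset_index(drop=True)
    )


def diff_expr_in_universe(
    norm_expr: np.ndarray,
    gene_names: Sequence[str],
    group_mask: np.ndarray,
    universe_genes: Sequence[str],
    lfc_min: float = 0.25,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential expression restricted to a gene universe.

    Per universe gene: Wilcoxon rank-sum p (group vs rest), log2 fold
    change of mean normalised expression, and Benjamini-Hochberg FDR
    across the universe.  ``de = (fdr_adjusted < fdr) & (|lfc| >= lfc_min)``.
    """
    X = np.asarray(norm_expr)
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.sum() == 0 or (~group_mask).sum() == 0:
        raise ValueError("both groups must be non-empty")
    idx_of = {g: i for i, g in enumerate(gene_names)}
    present = [g for g in universe_genes if g in idx_of]
    missing = [g for g in universe_genes if g not in idx_of]
    if not present:
        raise ValueError("empty universe after dropping absent genes")
    if missing:
        warnings.warn(f"universe: dropped {len(missing)} absent genes")
    cols = np.array([idx_of[g] for g in present])
    sub = X[:, cols]
    p = _rank_sum_genewise(sub, group_mask, ~group_mask)
    eps = 1e-9
    m1 = sub[group_mask].mean(axis=0)
    m0 = sub[~group_mask].mean(axis=0)
    lfc = np.log2((m1 + eps) / (m0 + eps))
    _, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    de = (p_adj < fdr) & (np.abs(lfc) >= lfc_min)
    return (
        pd.DataFrame(
            {
                "gene": present,
                "p_value": p,
                "fdr": p_adj,
                "log2_fc": lfc,
                "de": de,
            }
        )
        .sort_values(["de", "fdr"], ascending=[False, True])
        .reset_index(drop=True)
    )


def composition_table(cell_meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-state composition per sample and per condition.

    Returns ``(per_sample, per_state_delta)``: counts and fractions per
    (sample, condition, cell_state) with fractions summing to 1 within
    each sample, and the pooled per-state fraction difference
    lesional - nonlesional.
    """
    required = {"sample", "condition", "cell_state"}
    missing = required - set(cell_meta.columns)
    if missing:
        raise ValueError(f"cell_meta missing columns: {sorted(missing)}")
    counts = (
        cell_meta.groupby(["sample", "condition", "cell_state"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["fraction"] = counts["count"] / counts.groupby("sample")[
        "count"
    ].transform("sum")

    pooled = (
        cell_meta.groupby(["condition", "cell_state"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    pooled["fraction"] = pooled["count"] / pooled.groupby("condition")[
        "count"
    ].transform("sum")
    wide = pooled.pivot_table(
        index="cell_state", columns="condition", values="fraction", fill_value=0.0
    )
    for cond in ("nonlesional", "lesional"):
        if cond not in wide.columns:
            wide[cond] = 0.0
    delta = (
        (wide["lesional"] - wide["nonlesional"])
        .rename("delta_fraction")
        .reset_index()
    )
    return counts, delta
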