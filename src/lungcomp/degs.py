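"""Differential expression, tau specificity, stage modules and set scoring.

Differential expression follows the droplet-scRNA-seq convention: two-sided
Wilcoxon rank-sum per gene on log-normalized expression, natural-log fold
change of group means on the counts-per-10k scale, Benjamini–Hochberg
adjustment over all tested genes, and an up/down/unchanged call at
``|logFC| > threshold`` (0.25 for single-cell, 1 for bulk) with
``adjusted_p < alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .normalize import size_normalize

__all__ = [
    "differential_expression",
    "tau_specificity",
    "partition_shared_degs",
    "stage_modules",
    "gene_set_score",
    "GeneSetScore",
    "assign_by_max_score",
]


def _indexer(adata, cells) -> np.ndarray:
    idx = adata.obs_names.get_indexer(list(cells))
    if (idx < 0).any():
        raise ValueError("cell ids absent from the matrix")
    return idx


def differential_expression(
    expr,
    group_a,
    group_b,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two disjoint cell sets.

    Returns a frame indexed by gene with ``log_fc`` (natural log of the
    ratio of group mean CP10K + 1), ``p_value``, ``adjusted_p`` (BH) and
    ``direction``. Genes that are all-zero in both groups get p = 1 and
    log_fc = 0. log_fc > 0 means higher in ``group_a``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    norm = size_normalize(expr, scale=1e4)
    ia, ib = _indexer(expr, group_a), _indexer(expr, group_b)
    a, b = norm[ia], norm[ib]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    log_fc = np.log((mean_a + 1.0) / (mean_b + 1.0))

    # rank-sum is invariant to monotone transforms, so test on CP10K directly
    const = (a.max(axis=0) == a.min(axis=0)) & (b.max(axis=0) == b.min(axis=0)) \
        & (a[0] == b[0])
    p = np.ones(norm.shape[1])
    test_cols = ~const
    if test_cols.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = st.mannwhitneyu(
                a[:, test_cols], b[:, test_cols],
                alternative="two-sided", axis=0, method="asymptotic",
            )
        p[test_cols] = np.nan_to_num(res.pvalue, nan=1.0)
    log_fc[const] = 0.0
    adj = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        (log_fc > logfc_threshold) & (adj < alpha), "up",
        np.where((log_fc < -logfc_threshold) & (adj < alpha), "down", "unchanged"),
    )
    return pd.DataFrame(
        {"log_fc": log_fc, "p_value": p, "adjusted_p": adj, "direction": direction},
        index=pd.Index(expr.var_names, name="gene_id"),
    )


def tau_specificity(mean_expr_per_type) -> float:
    """Tau cell-specificity index of a non-negative per-type mean vector.

    tau = sum_i(1 - x_i / max(x)) / (n - 1): 0 for uniform expression, 1 for
    expression confined to a single type.
    """
    x = np.asarray(mean_expr_per_type, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau needs a 1-d vector over >= 2 types")
    if (x < 0).any():
        raise ValueError("tau is undefined for negative expression")
    m = x.max()
    if m == 0:
        raise ValueError("tau is undefined for an all-zero vector")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


def partition_shared_degs(deg_a: pd.DataFrame, deg_b: pd.DataFrame) -> dict:
    """Fractions of up-regulated genes specific to each table or shared.

    Fractions are over the union of the two up-sets and sum to 1; an empty
    union returns explicit zeros with ``n_union = 0``.
    """
    if not deg_a.index.equals(deg_b.index) and set(deg_a.index) != set(deg_b.index):
        raise ValueError("DEG tables cover different gene universes")
    up_a = set(deg_a.index[deg_a["direction"] == "up"])
    up_b = set(deg_b.index[deg_b["direction"] == "up"])
    union = up_a | up_b
    if not union:
        return {"a_specific": 0.0, "b_specific": 0.0, "shared": 0.0, "n_union": 0}
    n = len(union)
    return {
        "a_specific": len(up_a - up_b) / n,
        "b_specific": len(up_b - up_a) / n,
        "shared": len(up_a & up_b) / n,
        "n_union": n,
    }


def stage_modules(
    expr,
    stage_labels: pd.Series,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> pd.Series:
    """Assign each gene to the tumor stage where it is most up-regulated.

    One-vs-rest DE per stage; a gene joins the module of the stage with the
    largest log_fc among stages where it is called up, else ``none``. Stages
    with fewer than ``min_cells`` cells are excluded with a warning.
    """
    stage_labels = pd.Series(stage_labels)
    stages = [s for s in pd.unique(stage_labels) if pd.notna(s)]
    usable = []
    for s in stages:
        n = int((stage_labels == s).sum())
        if n < min_cells or (stage_labels != s).sum() < min_cells:
            warnings.warn(f"stage {s} excluded ({n} cells)", stacklevel=2)
        else:
            usable.append(s)
    if len(usable) < 2:
        raise ValueError("need >= 2 usable stages")
    lfc = {}
    for s in usable:
        cells_s = stage_labels.index[stage_labels == s]
        cells_rest = stage_labels.index[stage_labels != s]
        tab = differential_expression(
            expr, cells_s, cells_rest, logfc_threshold=logfc_threshold, alpha=alpha
        )
        lfc[s] = tab["log_fc"].where(tab["direction"] == "up", -np.inf)
    mat = pd.DataFrame(lfc)
    best = mat.idxmax(axis=1)
    best[mat.max(axis=1) == -np.inf] = "none"
    best.name = "module"
    return best


@dataclass
class GeneSetScore:
    scores: pd.Series
    gene_set_id: str
    transform: str                # "log2" or "identity"
    n_genes_used: int


def gene_set_score(
    expr,
    gene_set,
    log2_transform: bool = True,
    gene_set_id: str = "gene_set",
) -> GeneSetScore:
    """Per-cell mean normalized expression over a gene set.

    The score is the mean CP10K over the set's genes present in the matrix,
    log2(x + 1)-transformed when requested (the usual stemness-score form).
    An empty intersection is an error naming the set, never a silent 0.
    """
    present = [g for g in gene_set if g in set(expr.var_names)]
    if not present:
        raise ValueError(f"gene set '{gene_set_id}' shares no genes with the matrix")
    norm = size_normalize(expr, scale=1e4)
    cols = expr.var_names.get_indexer(present)
    s = norm[:, cols].mean(axis=1)
    if log2_transform:
        s = np.log2(s + 1.0)
    return GeneSetScore(
        scores=pd.Series(s, index=expr.obs_names, name=gene_set_id),
        gene_set_id=gene_set_id,
        transform="log2" if log2_transform else "identity",
        n_genes_used=len(present),
    )


def assign_by_max_score(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each cell to its maximal-score set, flagging exact ties.

    Ties go to the lexicographically first set name; returns columns
    ``label`` and ``tie``.
    """
    if scores.shape[1] < 1:
        raise ValueError("need at least one score column")
    ordered = scores[sorted(scores.columns)]
    vals = ordered.to_numpy()
    arg = vals.argmax(axis=1)
    ties = (vals == vals.max(axis=1, keepdims=True)).sum(axis=1) > 1
    return pd.DataFrame(
        {"label": np.array(ordered.columns)[arg], "tie": ties},
        index=scores.index,
    )
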