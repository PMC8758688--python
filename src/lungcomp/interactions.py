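"""Permutation-based ligand–receptor interaction scoring between cell types.

Follows the CellPhoneDB recipe: the interaction score of a (ligand,
receptor) pair from a sender to a receiver type is the mean of the ligand's
average normalized expression in the sender and the receptor's average in
the receiver. Significance comes from shuffling cell-type labels across all
cells; the test is one-sided for enrichment and the p-value lives on the
permutation grid (k + 1) / (B + 1). A pair is only evaluated when ligand
and receptor are detected in at least ``min_expressed_frac`` of the
sender / receiver cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import size_normalize

__all__ = [
    "LrPair",
    "InteractionResult",
    "interaction_score",
    "permutation_pvalue",
    "score_pairs",
    "count_interactions",
]


@dataclass(frozen=True)
class LrPair:
    ligand: str
    receptor: str
    pair_id: str | None = None

    def __post_init__(self):
        if self.pair_id is None:
            object.__setattr__(self, "pair_id", f"{self.ligand}__{self.receptor}")


@dataclass
class InteractionResult:
    pair_id: str
    sender: str
    receiver: str
    score: float
    p_value: float
    n_permutations: int
    flagged: bool = False           # too few cells, p forced to 1


def _gene_vector(expr, norm: np.ndarray, gene: str) -> np.ndarray:
    idx = expr.var_names.get_indexer([gene])[0]
    if idx < 0:
        raise ValueError(f"gene {gene} absent from expression matrix")
    return norm[:, idx]


def interaction_score(expr, pair: LrPair, sender: str, receiver: str) -> float:
    """Mean of sender ligand mean and receiver receptor mean expression."""
    norm = size_normalize(expr, scale=1e4)
    return _score_from_vectors(
        _gene_vector(expr, norm, pair.ligand),
        _gene_vector(expr, norm, pair.receptor),
        (expr.obs["cell_type"] == sender).to_numpy(),
        (expr.obs["cell_type"] == receiver).to_numpy(),
    )


def _score_from_vectors(lig, rec, sender_mask, receiver_mask) -> float:
    if not sender_mask.any():
        raise ValueError("sender type has no cells")
    if not receiver_mask.any():
        raise ValueError("receiver type has no cells")
    return float((lig[sender_mask].mean() + rec[receiver_mask].mean()) / 2.0)


def permutation_pvalue(
    expr,
    pair: LrPair,
    sender: str,
    receiver: str,
    n_permutations: int = 1000,
    seed: int = 0,
    _norm: np.ndarray | None = None,
) -> InteractionResult:
    """One-sided label-permutation p-value for one pair and type pair.

    Null scores come from reassigning cell-type labels uniformly at random
    across all cells; p = (#{null >= observed} + 1) / (B + 1). Fewer than 3
    cells in either type flags the result with p = 1.
    """
    if n_permutations < 100:
        raise ValueError("need >= 100 permutations")
    norm = size_normalize(expr, scale=1e4) if _norm is None else _norm
    lig = _gene_vector(expr, norm, pair.ligand)
    rec = _gene_vector(expr, norm, pair.receptor)
    s_mask = (expr.obs["cell_type"] == sender).to_numpy()
    r_mask = (expr.obs["cell_type"] == receiver).to_numpy()
    n_s, n_r = int(s_mask.sum()), int(r_mask.sum())
    obs = _score_from_vectors(lig, rec, s_mask, r_mask)
    if n_s < 3 or n_r < 3:
        return InteractionResult(
            pair.pair_id, sender, receiver, obs, 1.0, n_permutations, flagged=True
        )
    rng = np.random.default_rng(seed)
    n = len(lig)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        null = (lig[perm[:n_s]].mean() + rec[perm[n_s:n_s + n_r]].mean()) / 2.0
        if null >= obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return InteractionResult(pair.pair_id, sender, receiver, obs, p, n_permutations)


def score_pairs(
    expr,
    pairs: list[LrPair],
    type_pairs: list[tuple[str, str]] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    min_expressed_frac: float = 0.1,
) -> list[InteractionResult]:
    """Evaluate every (pair, sender, receiver) combination with the gate.

    ``type_pairs`` defaults to all ordered pairs of observed cell types. A
    pair is skipped for a type pair when the ligand (receptor) is detected
    in fewer than ``min_expressed_frac`` of sender (receiver) cells.
    """
    norm = size_normalize(expr, scale=1e4)
    types = sorted(pd.unique(expr.obs["cell_type"]))
    if type_pairs is None:
        type_pairs = [(s, r) for s in types for r in types]
    counts_pos = {}
    for t in types:
        counts_pos[t] = (expr.obs["cell_type"] == t).to_numpy()
    results = []
    rng = np.random.default_rng(seed)
    for pair in pairs:
        lig = _gene_vector(expr, norm, pair.ligand)
        rec = _gene_vector(expr, norm, pair.receptor)
        for sender, receiver in type_pairs:
            s_mask, r_mask = counts_pos[sender], counts_pos[receiver]
            if not s_mask.any() or not r_mask.any():
                continue
            if (lig[s_mask] > 0).mean() < min_expressed_frac:
                continue
            if (rec[r_mask] > 0).mean() < min_expressed_frac:
                continue
            results.append(
                permutation_pvalue(
                    expr, pair, sender, receiver,
                    n_permutations=n_permutations,
                    seed=int(rng.integers(2**31 - 1)),
                    _norm=norm,
                )
            )
    return results


def count_interactions(
    results: list[InteractionResult], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.Series]:
    """Significant-interaction counts per ordered type pair and per type.

    Returns the (sender x receiver) count matrix and per-type totals (sum
    over all pairs the type participates in, as sender or receiver).
    """
    types = sorted({r.sender for r in results} | {r.receiver for r in results})
    mat = pd.DataFrame(0, index=types, columns=types, dtype=int)
    for r in results:
        if r.p_value < alpha:
            mat.loc[r.sender, r.receiver] += 1
    per_type = pd.Series(0, index=types, dtype=int, name="n_interactions")
    for t in types:
        per_type[t] = int(mat.loc[t].sum() + mat[t].sum() - mat.loc[t, t])
    return mat, per_type
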