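"""Cell-type signature construction and bulk RNA-seq deconvolution.

The signature matrix holds, for a panel of cell-type-specific marker genes,
the mean linear-scale normalized expression per cell type. Markers are
chosen per type by one-vs-rest differential expression (BH-adjusted
p < 0.05), filtered by the tau specificity index, and ranked by fold
change. Bulk samples are decomposed as non-negative least-squares mixtures
of the signature columns (after per-gene unit-variance scaling), with the
weight vector renormalized to the unit simplex — making the estimate
invariant to the overall scale of each bulk sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats as st

from .degs import differential_expression, tau_specificity
from .normalize import size_normalize

__all__ = [
    "SignatureMatrix",
    "CompositionMatrix",
    "build_signature_matrix",
    "deconvolve",
    "evaluate_consistency",
]


@dataclass
class SignatureMatrix:
    """Marker genes x cell types reference expression, with provenance."""

    values: pd.DataFrame                 # genes x types, linear CP10K
    provenance: pd.DataFrame             # per gene: source_type, log_fc, tau

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CompositionMatrix:
    """Samples x cell types simplex weights plus per-sample fit residual."""

    weights: pd.DataFrame
    residual: pd.Series | None = None

    @property
    def cell_types(self) -> list[str]:
        return list(self.weights.columns)


def build_signature_matrix(
    expr,
    type_labels: pd.Series,
    n_markers_per_type: int = 50,
    tau_min: float = 0.6,
    alpha: float = 0.05,
) -> SignatureMatrix:
    """Select markers per cell type and assemble the reference matrix.

    Candidates per type are up-regulated one-vs-rest genes with
    ``adjusted_p < alpha`` and tau >= ``tau_min`` over the per-type mean
    expression, ranked by log fold change; the top ``n_markers_per_type``
    are kept. A type yielding no marker is an error naming the type.
    """
    type_labels = pd.Series(type_labels)
    types = sorted(pd.unique(type_labels))
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    norm = size_normalize(expr, scale=1e4)
    mean_by_type = pd.DataFrame(
        {t: norm[(type_labels == t).to_numpy()].mean(axis=0) for t in types},
        index=expr.var_names,
    )
    nonzero = mean_by_type.sum(axis=1) > 0
    tau = pd.Series(0.0, index=expr.var_names)
    tau[nonzero] = mean_by_type[nonzero].apply(
        lambda row: tau_specificity(row.to_numpy()), axis=1
    )
    chosen: list[pd.DataFrame] = []
    for t in types:
        cells_t = type_labels.index[type_labels == t]
        cells_rest = type_labels.index[type_labels != t]
        if len(cells_t) < 3:
            raise ValueError(f"cell type {t} has fewer than 3 cells")
        deg = differential_expression(expr, cells_t, cells_rest, alpha=alpha)
        cand = deg[(deg["direction"] == "up") & (tau.loc[deg.index] >= tau_min)]
        cand = cand.sort_values("log_fc", ascending=False).head(n_markers_per_type)
        if cand.empty:
            raise ValueError(f"no markers found for cell type {t}")
        prov = pd.DataFrame({
            "source_type": t,
            "log_fc": cand["log_fc"],
            "tau": tau.loc[cand.index],
        })
        chosen.append(prov)
    provenance = pd.concat(chosen)
    provenance = provenance[~provenance.index.duplicated(keep="first")]
    values = mean_by_type.loc[provenance.index, types]
    return SignatureMatrix(values=values, provenance=provenance)


def deconvolve(
    signature: SignatureMatrix,
    bulk: pd.DataFrame,
    min_overlap: float = 0.5,
) -> CompositionMatrix:
    """Estimate simplex cell-type weights for each bulk sample by NNLS.

    Shared genes are scaled to unit variance across signature columns, then
    ``min ||S w - b||_2, w >= 0`` is solved per sample and ``w`` normalized
    to sum 1. Signature genes missing from the bulk matrix are dropped; an
    overlap below ``min_overlap`` is an error reporting the fraction.
    """
    if (bulk.to_numpy() < 0).any():
        raise ValueError("bulk matrix must be non-negative")
    shared = signature.values.index.intersection(bulk.index)
    frac = len(shared) / len(signature.values.index)
    if frac < min_overlap:
        raise ValueError(
            f"only {frac:.1%} of signature genes present in bulk "
            f"(need >= {min_overlap:.0%})"
        )
    S = signature.values.loc[shared].to_numpy()
    B = bulk.loc[shared].to_numpy()
    sd = S.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    S_sc = S / sd[:, None]
    B_sc = B / sd[:, None]
    weights, residuals = [], []
    for j in range(B_sc.shape[1]):
        w, rnorm = scipy.optimize.nnls(S_sc, B_sc[:, j])
        total = w.sum()
        weights.append(w / total if total > 0 else np.full(len(w), 1 / len(w)))
        residuals.append(rnorm)
    return CompositionMatrix(
        weights=pd.DataFrame(
            weights, index=bulk.columns, columns=signature.values.columns
        ),
        residual=pd.Series(residuals, index=bulk.columns, name="residual"),
    )


def evaluate_consistency(
    comp_a: CompositionMatrix,
    comp_b: CompositionMatrix,
    pairing: dict | None = None,
) -> dict:
    """Pearson agreement of two composition estimates over paired samples.

    ``pairing`` maps sample names in ``comp_a`` to names in ``comp_b``
    (identity by default). Returns per-type r (NaN + flag for constant
    vectors) and the overall r over the flattened matrices.
    """
    a = comp_a.weights
    b = comp_b.weights
    if pairing is None:
        common = a.index.intersection(b.index)
        pairing = {s: s for s in common}
    if len(pairing) < 3:
        raise ValueError("need >= 3 paired samples")
    types = [t for t in a.columns if t in set(b.columns)]
    if not types:
        raise ValueError("no shared cell types")
    av = a.loc[list(pairing.keys()), types].to_numpy()
    bv = b.loc[list(pairing.values()), types].to_numpy()
    per_type, flagged = {}, []
    for i, t in enumerate(types):
        if np.ptp(av[:, i]) == 0 or np.ptp(bv[:, i]) == 0:
            per_type[t] = np.nan
            flagged.append(t)
        else:
            per_type[t] = float(st.pearsonr(av[:, i], bv[:, i])[0])
    overall = float(st.pearsonr(av.ravel(), bv.ravel())[0])
    return {
        "per_type_r": pd.Series(per_type, name="pearson_r"),
        "overall_r": overall,
        "constant_types": flagged,
    }
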