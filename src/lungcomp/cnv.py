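"""Expression-based CNV inference, malignancy calling and subclone clustering.

The profile follows the inferCNV idea: log-scale expression is centered
gene-wise on a non-malignant reference, averaged over sliding windows of
``window_size`` genes (step 1) in chromosome order, re-centered column-wise
on the reference, and clamped. Amplified regions then sit ~log2(multiplier)
above the reference baseline. A cell's CNV burden is its mean squared window
deviation; cells beyond ``mean + threshold_sd * SD`` of the reference burden
are called malignant. Malignant cells are grouped into subclones by Ward
clustering in window space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .normalize import log_normalize

__all__ = [
    "CnvProfile",
    "MalignancyCall",
    "SubcloneAssignment",
    "DriverScores",
    "compute_cnv_profile",
    "call_malignancy",
    "cluster_subclones",
    "score_driver_genes",
    "malignant_ratio",
]


@dataclass
class CnvProfile:
    """Cells x windows matrix of centered relative expression.

    ``windows`` maps each column to (chromosome, first/last order_index);
    ``reference`` is the non-malignant cell-id set the profile was centered
    on.
    """

    values: pd.DataFrame
    windows: pd.DataFrame
    reference: list[str]
    window_size: int
    clamp: float


@dataclass
class MalignancyCall:
    burden: pd.Series
    labels: pd.Series             # "malignant" / "non_malignant"
    threshold: float


@dataclass
class SubcloneAssignment:
    subclone: pd.Series           # contiguous ids 1..k over malignant cells
    k: int
    linkage: str = "ward"
    silhouette: float | None = None


@dataclass
class DriverScores:
    scores: pd.DataFrame          # subclones x driver genes
    missing: list[str] = field(default_factory=list)


def _chromosome_windows(n_genes: int, window_size: int) -> list[tuple[int, int]]:
    """Sliding windows (step 1) over one chromosome, inclusive local indices.

    Full windows of ``window_size`` genes; the chromosome tail keeps
    truncated windows of at least ``ceil(window_size / 2)`` genes. A
    chromosome shorter than that contributes one whole-chromosome window so
    no gene is silently dropped.
    """
    min_len = int(np.ceil(window_size / 2))
    out = []
    for i in range(n_genes):
        j = min(i + window_size, n_genes) - 1
        length = j - i + 1
        if length == window_size or length >= min_len:
            out.append((i, j))
    if not out:
        out = [(0, n_genes - 1)]
    return out


def compute_cnv_profile(
    expr,
    catalog: pd.DataFrame,
    reference_cells,
    window_size: int = 100,
    clamp: float = 3.0,
) -> CnvProfile:
    """Windowed, reference-centered relative-expression profile.

    ``expr`` is an AnnData of raw counts (cells x genes); genes are taken in
    catalog order (chromosome, then order_index), all-zero genes dropped.
    Expression scale is log2(counts-per-100k + 1) so that a dosage doubling
    shifts a fully covered window by ~1.

    Pipeline: gene-wise centering on the reference mean; sliding-window
    averaging; per-cell median subtraction (removes library-depth offsets);
    column re-centering on the reference; clamp of the window values to
    +/- ``clamp``.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("reference cell set is empty")
    missing_ref = set(reference_cells) - set(expr.obs_names)
    if missing_ref:
        raise ValueError(f"reference cells absent from matrix: {sorted(missing_ref)[:5]}")

    cat = catalog.sort_values(["chromosome", "order_index"], kind="stable")
    cat = cat[cat["gene_id"].isin(expr.var_names)].reset_index(drop=True)
    if cat.empty:
        raise ValueError("no expressed genes overlap the catalog")
    chroms_before = set(cat["chromosome"])
    sub = expr[:, cat["gene_id"].to_numpy()]
    logx = log_normalize(sub, scale=1e5, base=2.0)
    nonzero = logx.sum(axis=0) > 0
    logx = logx[:, nonzero]
    cat = cat.iloc[np.flatnonzero(nonzero)].reset_index(drop=True)
    dropped = chroms_before - set(cat["chromosome"])
    if dropped:
        raise ValueError(f"no expressed genes retained on {sorted(dropped)}")

    ref_idx = expr.obs_names.get_indexer(reference_cells)
    centered = logx - logx[ref_idx].mean(axis=0, keepdims=True)

    cols, win_rows = [], []
    for chrom in cat["chromosome"].unique():
        mask = (cat["chromosome"] == chrom).to_numpy()
        order = cat.loc[mask, "order_index"].to_numpy()
        block = centered[:, mask]
        csum = np.concatenate(
            [np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1
        )
        for i, j in _chromosome_windows(block.shape[1], window_size):
            cols.append((csum[:, j + 1] - csum[:, i]) / (j - i + 1))
            win_rows.append((chrom, int(order[i]), int(order[j])))
    values = np.column_stack(cols)
    # remove per-cell offsets (library-depth artifacts), then re-center the
    # columns on the reference so its window means are exactly zero
    values = values - np.median(values, axis=1, keepdims=True)
    values = values - values[ref_idx].mean(axis=0, keepdims=True)
    values = np.clip(values, -clamp, clamp)
    windows = pd.DataFrame(win_rows, columns=["chromosome", "first_gene", "last_gene"])
    windows.index = [
        f"{c}:{a}-{b}" for c, a, b in windows.itertuples(index=False)
    ]
    vdf = pd.DataFrame(values, index=expr.obs_names, columns=windows.index)
    return CnvProfile(
        values=vdf, windows=windows, reference=reference_cells,
        window_size=window_size, clamp=clamp,
    )


def call_malignancy(profile: CnvProfile, threshold_sd: float = 3.0) -> MalignancyCall:
    """Label cells whose CNV burden exceeds the reference by ``threshold_sd`` SD.

    Burden is the mean squared window deviation per cell; the threshold is
    the mean + ``threshold_sd`` x SD of the reference cells' own burden.
    """
    burden = (profile.values ** 2).mean(axis=1)
    ref = burden.loc[profile.reference]
    if ref.std(ddof=1) == 0:
        raise ValueError(
            "reference burden has zero variance — degenerate reference "
            f"({len(profile.reference)} cells)"
        )
    threshold = float(ref.mean() + threshold_sd * ref.std(ddof=1))
    labels = pd.Series(
        np.where(burden > threshold, "malignant", "non_malignant"),
        index=burden.index, name="label",
    )
    return MalignancyCall(burden=burden, labels=labels, threshold=threshold)


def cluster_subclones(
    profile: CnvProfile,
    malignant_cells,
    k: int | str = "auto",
    k_max: int = 8,
) -> SubcloneAssignment:
    """Ward clustering of malignant cells in window space.

    ``k='auto'`` picks k in 2..k_max by silhouette. Cells are processed in
    lexicographic id order so dendrogram ties resolve deterministically;
    subclone ids 1..k are assigned by order of first appearance.
    """
    cells = sorted(malignant_cells)
    X = profile.values.loc[cells].to_numpy()
    if k == "auto":
        best, best_score = None, -np.inf
        for kk in range(2, min(k_max, len(cells) - 1) + 1):
            lab = AgglomerativeClustering(n_clusters=kk, linkage="ward").fit_predict(X)
            s = silhouette_score(X, lab)
            if s > best_score + 1e-12:
                best, best_score = kk, s
        if best is None:
            best, best_score = 1, None
        k, sil = best, best_score
    else:
        k = int(k)
        sil = None
        if k > len(cells):
            raise ValueError(f"k={k} exceeds the {len(cells)} malignant cells")
    if k == 1:
        raw = np.zeros(len(cells), dtype=int)
    else:
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    remap, nxt = {}, 1
    ids = np.empty(len(cells), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        ids[i] = remap[lab]
    return SubcloneAssignment(
        subclone=pd.Series(ids, index=cells, name="subclone"),
        k=k, silhouette=sil,
    )


def score_driver_genes(
    profile: CnvProfile,
    assignment: SubcloneAssignment,
    driver_genes,
    catalog: pd.DataFrame,
) -> DriverScores:
    """Average inferred-CNV score of each driver gene per subclone.

    A gene's cell-level score is the mean over all windows containing it;
    the reported score averages that over the subclone's cells. Drivers
    absent from the catalog are reported in ``missing`` with a warning, not
    silently dropped.
    """
    cat = catalog.set_index("gene_id")
    missing = [g for g in driver_genes if g not in cat.index]
    if missing:
        warnings.warn(f"driver genes not in catalog: {missing}", stacklevel=2)
    present = [g for g in driver_genes if g in cat.index]
    rows = {}
    for sub_id in sorted(assignment.subclone.unique()):
        cells = assignment.subclone.index[assignment.subclone == sub_id]
        sub_vals = profile.values.loc[cells]
        scores = {}
        for g in present:
            chrom, pos = cat.loc[g, "chromosome"], cat.loc[g, "order_index"]
            w = profile.windows
            hit = w.index[
                (w["chromosome"] == chrom)
                & (w["first_gene"] <= pos)
                & (w["last_gene"] >= pos)
            ]
            scores[g] = float(sub_vals[hit].to_numpy().mean()) if len(hit) else np.nan
        rows[sub_id] = scores
    return DriverScores(
        scores=pd.DataFrame.from_dict(rows, orient="index")[present]
        if present else pd.DataFrame(index=list(rows)),
        missing=missing,
    )


def malignant_ratio(calls: MalignancyCall, cell_types: pd.Series) -> pd.DataFrame:
    """Malignant : non-malignant cell-count ratio per cell type.

    When a type has zero non-malignant cells the ratio uses a +0.5
    continuity correction on both counts and the row is flagged.
    """
    df = pd.DataFrame({
        "label": calls.labels, "cell_type": cell_types.loc[calls.labels.index],
    })
    rows = []
    for t, grp in df.groupby("cell_type", observed=True):
        m = int((grp["label"] == "malignant").sum())
        nm = int((grp["label"] == "non_malignant").sum())
        if nm == 0:
            rows.append((t, m, nm, (m + 0.5) / 0.5, True))
        else:
            rows.append((t, m, nm, m / nm, False))
    return pd.DataFrame(
        rows, columns=["cell_type", "n_malignant", "n_non_malignant", "ratio",
                       "corrected"],
    ).set_index("cell_type")
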