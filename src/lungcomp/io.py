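"""Plain-text readers/writers for the cohort's on-disk layout.

Single-cell counts travel as Matrix Market (MTX) with ``genes.tsv`` /
``barcodes.tsv`` sidecars, gene coordinates as BED (0-based half-open),
bulk expression as a genes x samples TSV, and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .synthetic import CnvEvent, SyntheticTruth

__all__ = [
    "write_cohort",
    "read_single_cells",
    "write_gene_bed",
    "read_gene_bed",
    "write_truth",
    "read_truth",
]


def write_cohort(
    out_dir,
    adata: ad.AnnData,
    catalog: pd.DataFrame,
    bulk: pd.DataFrame | None = None,
    truth: SyntheticTruth | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.csr_matrix(adata.X).T)  # genes x cells
    adata.var.reset_index().to_csv(out / "genes.tsv", sep="\t", index=False)
    adata.obs.reset_index().rename(columns={"index": "cell_id"}).to_csv(
        out / "barcodes.tsv", sep="\t", index=False
    )
    write_gene_bed(out / "genes.bed", catalog)
    if bulk is not None:
        bulk.to_csv(out / "bulk.tsv", sep="\t")
    if truth is not None:
        write_truth(out / "truth.json", truth)


def read_single_cells(in_dir) -> ad.AnnData:
    d = Path(in_dir)
    X = scipy.io.mmread(d / "matrix.mtx").T.tocsr()   # back to cells x genes
    var = pd.read_csv(d / "genes.tsv", sep="\t").set_index("gene_id")
    obs = pd.read_csv(d / "barcodes.tsv", sep="\t").set_index("cell_id")
    return ad.AnnData(X=X, obs=obs, var=var)


def write_gene_bed(path, catalog: pd.DataFrame) -> None:
    """0-based half-open BED: chrom, start, end, gene_id, order_index."""
    bed = pd.DataFrame({
        "chrom": catalog["chromosome"],
        "start": catalog["start"],
        "end": catalog["start"] + 1_000,   # nominal 1 kb gene body
        "name": catalog["gene_id"],
        "score": catalog["order_index"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score"],
    )
    return pd.DataFrame({
        "gene_id": bed["name"],
        "chromosome": bed["chrom"],
        "start": bed["start"],
        "order_index": bed["score"].astype(int),
    })


def write_truth(path, truth: SyntheticTruth) -> None:
    payload: dict = {}
    if truth.cell_malignant is not None:
        payload["cell_malignant"] = {
            k: bool(v) for k, v in truth.cell_malignant.items()
        }
        payload["cell_subclone"] = {
            k: int(v) for k, v in truth.cell_subclone.items()
        }
    if truth.markers:
        payload["markers"] = truth.markers
    if truth.cnv_events:
        payload["cnv_events"] = [
            {
                "chromosome": e.chromosome,
                "first_gene": e.first_gene,
                "last_gene": e.last_gene,
                "multiplier": e.multiplier,
                "subclone_id": e.subclone_id,
            }
            for e in truth.cnv_events
        ]
    if truth.bulk_composition is not None:
        payload["bulk_composition"] = {
            s: {t: float(w) for t, w in row.items()}
            for s, row in truth.bulk_composition.iterrows()
        }
        payload["bulk_group"] = dict(truth.bulk_group)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    truth = SyntheticTruth()
    if "cell_malignant" in payload:
        truth.cell_malignant = pd.Series(payload["cell_malignant"])
        truth.cell_subclone = pd.Series(payload["cell_subclone"])
    truth.markers = payload.get("markers", {})
    truth.cnv_events = [CnvEvent(**e) for e in payload.get("cnv_events", [])]
    if "bulk_composition" in payload:
        truth.bulk_composition = pd.DataFrame.from_dict(
            payload["bulk_composition"], orient="index"
        )
        truth.bulk_group = pd.Series(payload["bulk_group"], name="group")
    return truth
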