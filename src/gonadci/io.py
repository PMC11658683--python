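"""Reading and writing the CellRanger-style MTX triplet plus cell metadata.

Layout of a fixture directory::

    matrix.mtx    MatrixMarket coordinate matrix, genes x cells
    features.tsv  one gene per line (id, name)
    barcodes.tsv  one cell barcode per line
    cells.tsv     tab-separated per-cell metadata with header

The in-memory container is :class:`anndata.AnnData` (cells x genes); the
on-disk matrix follows the genes-x-cells CellRanger convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

_CELL_META_COLUMNS = [
    "sample_id", "genotype", "stage", "cell_type", "total_counts",
    "n_genes_expressed", "pct_mito", "phase", "sci", "gci", "is_dp", "dp_truth",
]


def write_fixture(adata: ad.AnnData, directory: str | Path, field: str = "integer") -> Path:
    """Write ``adata`` as an MTX triplet plus ``cells.tsv``; round-trips with
    :func:`read_fixture`.  ``field='real'`` writes a real-valued matrix (for
    normalized data)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    mat = X.T.tocoo()  # genes x cells on disk
    if field == "integer":
        mat = mat.astype(np.int64)
    scipy.io.mmwrite(directory / "matrix.mtx", mat, field=field)
    with open(directory / "features.tsv", "w") as fh:
        for g in adata.var_names:
            fh.write(f"{g}\t{g}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for c in adata.obs_names:
            fh.write(f"{c}\n")
    cols = [c for c in _CELL_META_COLUMNS if c in adata.obs.columns]
    extra = [c for c in adata.obs.columns if c not in cols]
    adata.obs[cols + extra].to_csv(
        directory / "cells.tsv", sep="\t", index=True, index_label="cell_id"
    )
    return directory


def read_fixture(directory: str | Path) -> ad.AnnData:
    """Read a fixture directory written by :func:`write_fixture` (or any
    CellRanger-style triplet accompanied by a ``cells.tsv``)."""
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    X = sp.csr_matrix(mat).T  # cells x genes in memory
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)
    gene_ids = features[0].astype(str).tolist()
    with open(directory / "barcodes.tsv") as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene identifiers in features.tsv")
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate cell barcodes in barcodes.tsv")
    obs = pd.DataFrame(index=pd.Index(barcodes))
    cells_path = directory / "cells.tsv"
    if cells_path.exists():
        meta = pd.read_csv(cells_path, sep="\t", index_col="cell_id")
        obs = meta.reindex(barcodes)
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(gene_ids))
    )
    return adata


def save_model(model: dict, path: str | Path) -> None:
    """Serialize a fitted identity or ICA model description to JSON."""
    with open(path, "w") as fh:
        json.dump(model, fh, indent=1, default=_jsonable)


def load_model(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
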