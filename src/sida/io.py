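"""Reading/writing batches, collections and embeddings; label consolidation.

Supported on-disk formats
-------------------------
* ``csv`` -- one dense delimited file per batch: header row of gene names,
  index column of cell ids, plus a label column (default ``cell_type``).
* ``mtx`` -- MatrixMarket triplet per batch (cells x genes) with sidecars
  ``<stem>_barcodes.tsv``, ``<stem>_genes.tsv``, ``<stem>_labels.tsv``.
* ``h5ad`` -- AnnData file per batch with labels in ``obs`` (default field
  ``cell_type``) and optionally the batch id in ``obs['batch']``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import DataCollection, Embedding, ExpressionBatch

__all__ = [
    "consolidate_labels",
    "read_collection",
    "write_collection",
    "read_embedding",
    "write_embedding",
]


def consolidate_labels(
    collection: DataCollection, label_map: dict[str, str]
) -> DataCollection:
    """Apply a raw-label -> consolidated-label mapping to every batch.

    Cell-type vocabularies differ across studies ("DCs", "DC",
    "Dendritic Cells"); integration requires one consolidated vocabulary at
    the most general level shared by the batches.  The mapping is supplied
    explicitly by the user and validated for completeness: every raw label
    occurring in any batch must have an entry (identity entries allowed).

    Idempotent on already-consolidated input given an identity mapping.
    Never changes matrix values or cell order.
    """
    missing: dict[str, list[str]] = {}
    for b in collection.batches:
        absent = sorted({t for t in b.cell_types if t not in label_map})
        if absent:
            missing[b.batch_id] = absent
    if missing:
        desc = "; ".join(f"batch {k!r}: {v}" for k, v in missing.items())
        raise ValueError(f"unmapped cell type labels: {desc}")
    new_batches = []
    for b in collection.batches:
        new_types = np.array([label_map[t] for t in b.cell_types], dtype=object)
        new_batches.append(
            ExpressionBatch(b.matrix, b.gene_names, b.cell_ids, new_types, b.batch_id)
        )
    return DataCollection(new_batches, label_map=dict(label_map), is_log=collection.is_log)


# ---------------------------------------------------------------------------
# collection I/O


def _read_csv_batch(path: Path, label_field: str, batch_id: str) -> ExpressionBatch:
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as e:  # pragma: no cover - message path
        raise ValueError(f"failed to parse {path}: {e}") from e
    if label_field not in df.columns:
        raise ValueError(f"{path}: missing label column {label_field!r}")
    labels = df[label_field].astype(str).to_numpy(dtype=object)
    mat = df.drop(columns=[label_field])
    return ExpressionBatch(
        matrix=mat.to_numpy(dtype=float),
        gene_names=mat.columns.to_numpy(dtype=object),
        cell_ids=df.index.to_numpy(dtype=object),
        cell_types=labels,
        batch_id=batch_id,
    )


def _sidecar(path: Path, suffix: str) -> Path:
    return path.with_name(path.name.replace(".mtx", "") + suffix)


def _read_mtx_batch(path: Path, batch_id: str) -> ExpressionBatch:
    mat = scipy.io.mmread(path)
    mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    barcodes = pd.read_csv(_sidecar(path, "_barcodes.tsv"), header=None, sep="\t")[0]
    genes = pd.read_csv(_sidecar(path, "_genes.tsv"), header=None, sep="\t")[0]
    labels = pd.read_csv(_sidecar(path, "_labels.tsv"), header=None, sep="\t")[0]
    if len(barcodes) != mat.shape[0]:
        raise ValueError(
            f"{path}: matrix has {mat.shape[0]} rows but {len(barcodes)} barcodes"
        )
    if len(labels) != mat.shape[0]:
        raise ValueError(
            f"{path}: matrix has {mat.shape[0]} rows but {len(labels)} labels"
        )
    if len(genes) != mat.shape[1]:
        raise ValueError(
            f"{path}: matrix has {mat.shape[1]} columns but {len(genes)} genes"
        )
    return ExpressionBatch(
        matrix=mat,
        gene_names=genes.to_numpy(dtype=object),
        cell_ids=barcodes.to_numpy(dtype=object),
        cell_types=labels.astype(str).to_numpy(dtype=object),
        batch_id=batch_id,
    )


def _read_h5ad_batch(path: Path, label_field: str, batch_id: str) -> ExpressionBatch:
    import anndata as ad

    adata = ad.read_h5ad(path)
    if label_field not in adata.obs.columns:
        raise ValueError(f"{path}: missing obs field {label_field!r}")
    X = adata.X
    X = np.asarray(X.todense() if scipy.sparse.issparse(X) else X, dtype=float)
    if "batch" in adata.obs.columns:
        vals = adata.obs["batch"].astype(str).unique()
        if len(vals) == 1:
            batch_id = vals[0]
    return ExpressionBatch(
        matrix=X,
        gene_names=adata.var_names.to_numpy(dtype=object),
        cell_ids=adata.obs_names.to_numpy(dtype=object),
        cell_types=adata.obs[label_field].astype(str).to_numpy(dtype=object),
        batch_id=batch_id,
    )


def read_collection(
    paths: list[str | os.PathLike],
    format: str = "csv",
    label_field: str = "cell_type",
    batch_ids: list[str] | None = None,
) -> DataCollection:
    """Read one batch per file into a :class:`DataCollection`.

    Gene order is preserved exactly as stored; batch ids default to the file
    stems.
    """
    paths = [Path(p) for p in paths]
    if batch_ids is None:
        batch_ids = [p.name.split(".")[0] for p in paths]
    batches = []
    for p, bid in zip(paths, batch_ids):
        if not p.exists():
            raise FileNotFoundError(p)
        if format == "csv":
            batches.append(_read_csv_batch(p, label_field, bid))
        elif format == "mtx":
            batches.append(_read_mtx_batch(p, bid))
        elif format == "h5ad":
            batches.append(_read_h5ad_batch(p, label_field, bid))
        else:
            raise ValueError(f"unknown format {format!r}")
    return DataCollection(batches)


def write_collection(
    collection: DataCollection,
    outdir: str | os.PathLike,
    format: str = "csv",
    label_field: str = "cell_type",
) -> list[Path]:
    """Write each batch to ``outdir`` in the requested format.

    Round-trips losslessly with :func:`read_collection` for all formats.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for b in collection.batches:
        if format == "csv":
            path = outdir / f"{b.batch_id}.csv"
            df = pd.DataFrame(b.matrix, index=b.cell_ids, columns=b.gene_names)
            df.insert(0, label_field, b.cell_types)
            df.to_csv(path)
        elif format == "mtx":
            path = outdir / f"{b.batch_id}.mtx"
            scipy.io.mmwrite(path, scipy.sparse.csr_matrix(b.matrix))
            pd.Series(b.cell_ids).to_csv(_sidecar(path, "_barcodes.tsv"), index=False, header=False)
            pd.Series(b.gene_names).to_csv(_sidecar(path, "_genes.tsv"), index=False, header=False)
            pd.Series(b.cell_types).to_csv(_sidecar(path, "_labels.tsv"), index=False, header=False)
        elif format == "h5ad":
            import anndata as ad

            path = outdir / f"{b.batch_id}.h5ad"
            adata = ad.AnnData(
                X=b.matrix.copy(),
                obs=pd.DataFrame(
                    {label_field: b.cell_types.astype(str), "batch": b.batch_id},
                    index=b.cell_ids.astype(str),
                ),
                var=pd.DataFrame(index=b.gene_names.astype(str)),
            )
            adata.write_h5ad(path)
        else:
            raise ValueError(f"unknown format {format!r}")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# embedding I/O


def write_embedding(embedding: Embedding, path: str | os.PathLike) -> Path:
    """Write an embedding as a TSV of cell_id, batch_id, cell_type, dim0..dimD.

    Full float precision is preserved so read-back equals the input exactly.
    """
    if embedding.n_cells == 0:
        raise ValueError("refusing to write an empty embedding")
    path = Path(path)
    embedding.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_embedding(path: str | os.PathLike) -> Embedding:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    dim_cols = [c for c in df.columns if c.startswith("dim")]
    if not dim_cols:
        raise ValueError(f"{path}: no coordinate columns (dim0, dim1, ...)")
    return Embedding(
        coords=df[dim_cols].to_numpy(dtype=float),
        cell_ids=df["cell_id"].to_numpy(dtype=object),
        cell_types=df["cell_type"].astype(str).to_numpy(dtype=object),
        batch_ids=df["batch_id"].astype(str).to_numpy(dtype=object),
    )
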