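"""Gene intersection, library-size normalization, log transform, per-batch PCA.

Pipeline order is fixed: intersect -> normalize -> log -> PCA.  Each batch is
reduced to its own top principal components (default 50) computed on its own
centered data; the per-batch coordinate systems are deliberately NOT aligned
with each other -- alignment is the integration network's task, and working
from independently computed PCs is the harder variant of the problem compared
to a shared highly-variable-gene space.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .datatypes import DataCollection, ExpressionBatch, PCView

__all__ = [
    "intersect_genes",
    "normalize_log",
    "pca_per_batch",
    "preprocess_collection",
    "save_pc_view",
    "load_pc_view",
]


def intersect_genes(collection: DataCollection) -> DataCollection:
    """Restrict every batch to the shared gene set, in sorted order.

    Genes are matched by exact identifier string; no alias resolution.
    """
    if len(collection.batches) < 2:
        raise ValueError("need >= 2 batches to intersect genes")
    shared = set(collection.batches[0].gene_names)
    for b in collection.batches[1:]:
        shared &= set(b.gene_names)
    if not shared:
        raise ValueError("gene intersection across batches is empty")
    canon = np.array(sorted(shared), dtype=object)
    new_batches = []
    for b in collection.batches:
        pos = {g: i for i, g in enumerate(b.gene_names)}
        idx = np.array([pos[g] for g in canon])
        new_batches.append(
            ExpressionBatch(b.matrix[:, idx], canon.copy(), b.cell_ids, b.cell_types, b.batch_id)
        )
    return DataCollection(new_batches, label_map=collection.label_map, is_log=collection.is_log)


def normalize_log(
    batch: ExpressionBatch, scale: float = 10_000.0, drop_zero_cells: bool = False
) -> ExpressionBatch:
    """Library-size normalize each cell to total ``scale``, then log1p.

    Raises on negative input; a zero library size raises by default or drops
    the cell with a warning when ``drop_zero_cells`` is set.
    """
    m = batch.matrix
    if np.any(m < 0):
        raise ValueError(f"batch {batch.batch_id!r}: negative expression values")
    lib = m.sum(axis=1)
    zero = lib == 0
    if zero.any():
        if not drop_zero_cells:
            raise ValueError(
                f"batch {batch.batch_id!r}: {int(zero.sum())} cells with zero library size"
            )
        warnings.warn(
            f"batch {batch.batch_id!r}: dropping {int(zero.sum())} zero-count cells"
        )
        batch = batch.subset_cells(~zero)
        m = batch.matrix
        lib = m.sum(axis=1)
    normed = m * (scale / lib)[:, None]
    return replace(batch, matrix=np.log1p(normed))


def pca_per_batch(collection: DataCollection, n_pcs: int = 50) -> PCView:
    """Center each batch on its own gene means and keep its top ``n_pcs`` PCs.

    Uses exact SVD; components are ordered by decreasing explained variance.
    Deterministic sign convention: the largest-magnitude loading of each
    component is forced positive, so repeated runs and platforms agree.

    If any batch has fewer than ``n_pcs + 1`` cells or ``n_pcs`` genes,
    ``n_pcs`` is lowered globally with a warning so all batches share one
    dimensionality.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    cap = min(min(b.n_cells - 1, b.n_genes) for b in collection.batches)
    if cap < n_pcs:
        warnings.warn(f"lowering n_pcs from {n_pcs} to {cap} (smallest batch limit)")
        n_pcs = cap
    coords, loadings, means, evs = [], [], [], []
    for b in collection.batches:
        mu = b.matrix.mean(axis=0)
        Xc = b.matrix - mu
        # exact thin SVD; columns of Vt.T are the principal axes
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        V = Vt[:n_pcs].T  # (genes, n_pcs)
        # sign convention: largest-|loading| entry of each component positive
        flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(n_pcs)])
        flip[flip == 0] = 1.0
        V = V * flip
        coords.append(Xc @ V)
        loadings.append(V)
        means.append(mu)
        evs.append((S[:n_pcs] ** 2) / (b.n_cells - 1))
    return PCView(
        coords=coords,
        cell_ids=[b.cell_ids for b in collection.batches],
        cell_types=[b.cell_types for b in collection.batches],
        batch_ids=collection.batch_ids,
        n_pcs=n_pcs,
        loadings=loadings,
        means=means,
        explained_variance=evs,
    )


def save_pc_view(view: PCView, outdir) -> None:
    """Serialize a PC view: per-batch TSV of coordinates plus a JSON sidecar
    (n_pcs, per-batch gene means and explained variance)."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for bi, bid in enumerate(view.batch_ids):
        df = pd.DataFrame(
            view.coords[bi], columns=[f"pc{j}" for j in range(view.n_pcs)]
        )
        df.insert(0, "cell_id", view.cell_ids[bi])
        df.insert(1, "cell_type", view.cell_types[bi])
        df.to_csv(outdir / f"{bid}.pcs.tsv", sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "n_pcs": view.n_pcs,
        "batch_ids": list(view.batch_ids),
        "means": None if view.means is None else [m.tolist() for m in view.means],
        "explained_variance": None
        if view.explained_variance is None
        else [e.tolist() for e in view.explained_variance],
    }
    (outdir / "pc_view.json").write_text(json.dumps(sidecar))


def load_pc_view(outdir) -> PCView:
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    sidecar = json.loads((outdir / "pc_view.json").read_text())
    coords, cids, ctypes = [], [], []
    for bid in sidecar["batch_ids"]:
        df = pd.read_csv(outdir / f"{bid}.pcs.tsv", sep="\t", float_precision="round_trip")
        coords.append(df[[f"pc{j}" for j in range(sidecar["n_pcs"])]].to_numpy(float))
        cids.append(df["cell_id"].to_numpy(dtype=object))
        ctypes.append(df["cell_type"].astype(str).to_numpy(dtype=object))
    return PCView(
        coords=coords,
        cell_ids=cids,
        cell_types=ctypes,
        batch_ids=list(sidecar["batch_ids"]),
        n_pcs=sidecar["n_pcs"],
        means=None if sidecar["means"] is None else [np.array(m) for m in sidecar["means"]],
        explained_variance=None
        if sidecar["explained_variance"] is None
        else [np.array(e) for e in sidecar["explained_variance"]],
    )


def preprocess_collection(
    collection: DataCollection,
    n_pcs: int = 50,
    scale: float = 10_000.0,
    normalize: bool | None = None,
) -> tuple[DataCollection, PCView]:
    """Full pipeline: intersect genes, normalize+log (for count data), PCA.

    ``normalize=None`` (default) infers from ``collection.is_log``: matrices
    already on log scale skip library-size normalization and log transform.
    Returns the gene-space collection actually fed to PCA (the reference
    projection step later needs those gene-space values) and the PC view.
    """
    if normalize is None:
        normalize = not collection.is_log
    inter = intersect_genes(collection)
    if normalize:
        if inter.is_log:
            raise ValueError("collection is already log-scale; refusing to normalize again")
        inter = DataCollection(
            [normalize_log(b, scale=scale) for b in inter.batches],
            label_map=inter.label_map,
            is_log=True,
        )
    return inter, pca_per_batch(inter, n_pcs=n_pcs)
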