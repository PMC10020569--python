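"""Core in-memory containers shared by all pipeline stages.

The package stores every matrix cells-by-genes (rows are cells); all
modules rely on this single orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionBatch",
    "DataCollection",
    "PCView",
    "PairBatch",
    "PairSchedule",
    "Embedding",
]


@dataclass
class ExpressionBatch:
    """One scRNA-seq batch: expression matrix plus per-cell annotations.

    Parameters
    ----------
    matrix
        ``(n_cells, n_genes)`` nonnegative expression values (raw counts or
        already log-scale values, depending on provenance).
    gene_names
        Ordered gene identifiers, unique within the batch.
    cell_ids
        Ordered per-cell identifiers.
    cell_types
        Per-cell cell-type label strings.
    batch_id
        Identifier of the batch (the "domain" in domain-adaptation terms).
    """

    matrix: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    cell_types: np.ndarray
    batch_id: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x genes)")
        n, g = self.matrix.shape
        if not (len(self.cell_ids) == len(self.cell_types) == n):
            raise ValueError(
                f"batch {self.batch_id!r}: {n} matrix rows but "
                f"{len(self.cell_ids)} cell_ids / {len(self.cell_types)} cell_types"
            )
        if len(self.gene_names) != g:
            raise ValueError(
                f"batch {self.batch_id!r}: {g} matrix columns but "
                f"{len(self.gene_names)} gene names"
            )
        if len(set(self.gene_names)) != g:
            raise ValueError(f"batch {self.batch_id!r}: duplicate gene names")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "ExpressionBatch":
        return replace(
            self,
            matrix=self.matrix[idx],
            cell_ids=self.cell_ids[idx],
            cell_types=self.cell_types[idx],
        )


@dataclass
class DataCollection:
    """A set of batches to integrate, plus the label-consolidation record.

    ``label_map`` maps raw annotation strings to consolidated labels; it is
    empty until :func:`sida.io.consolidate_labels` has been applied.
    """

    batches: list[ExpressionBatch]
    label_map: dict[str, str] = field(default_factory=dict)
    is_log: bool = False  # True if matrices are already on log scale

    def __post_init__(self) -> None:
        ids = [b.batch_id for b in self.batches]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate batch ids: {ids}")

    @property
    def batch_ids(self) -> list[str]:
        return [b.batch_id for b in self.batches]

    @property
    def cell_type_universe(self) -> list[str]:
        """Sorted consolidated cell-type labels present in the collection."""
        u: set[str] = set()
        for b in self.batches:
            u.update(b.cell_types.tolist())
        return sorted(u)

    @property
    def n_cells(self) -> int:
        return sum(b.n_cells for b in self.batches)

    def get_batch(self, batch_id: str) -> ExpressionBatch:
        for b in self.batches:
            if b.batch_id == batch_id:
                return b
        raise KeyError(f"no batch {batch_id!r} in collection")


@dataclass
class PCView:
    """Per-batch principal-component coordinates feeding the network.

    Each batch is reduced independently, so the coordinate systems of the
    batches are NOT mutually aligned -- aligning them is the integration
    network's job.
    """

    coords: list[np.ndarray]  # per batch: (n_cells, n_pcs)
    cell_ids: list[np.ndarray]
    cell_types: list[np.ndarray]
    batch_ids: list[str]
    n_pcs: int
    loadings: list[np.ndarray] | None = None  # per batch: (n_genes, n_pcs)
    means: list[np.ndarray] | None = None  # per batch gene means
    explained_variance: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        for c in self.coords:
            if c.shape[1] != self.n_pcs:
                raise ValueError("all batches must share n_pcs")

    @property
    def n_batches(self) -> int:
        return len(self.coords)

    def batch_index(self, batch_id: str) -> int:
        return self.batch_ids.index(batch_id)

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Concatenate all batches: (X, cell_ids, cell_types, batch_id per cell)."""
        X = np.vstack(self.coords)
        ids = np.concatenate(self.cell_ids)
        types = np.concatenate(self.cell_types)
        batches = np.concatenate(
            [np.full(len(c), bid, dtype=object) for c, bid in zip(self.coords, self.batch_ids)]
        )
        return X, ids, types, batches

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        cell_types: np.ndarray,
        batches: np.ndarray,
        cell_ids: np.ndarray | None = None,
    ) -> "PCView":
        """Build a view from stacked arrays (one row per cell)."""
        X = np.asarray(X, dtype=float)
        cell_types = np.asarray(cell_types, dtype=object)
        batches = np.asarray(batches, dtype=object)
        if cell_ids is None:
            cell_ids = np.array([f"cell{i}" for i in range(len(X))], dtype=object)
        order = pd.unique(batches)
        coords, cids, ctypes = [], [], []
        for b in order:
            m = batches == b
            coords.append(X[m])
            cids.append(np.asarray(cell_ids, dtype=object)[m])
            ctypes.append(cell_types[m])
        return cls(
            coords=coords,
            cell_ids=cids,
            cell_types=ctypes,
            batch_ids=[str(b) for b in order],
            n_pcs=X.shape[1],
        )


@dataclass
class PairBatch:
    """A minibatch of cross-batch training pairs for the Siamese network."""

    x_source: np.ndarray  # (size, n_pcs)
    x_target: np.ndarray  # (size, n_pcs)
    y_source: np.ndarray  # (size,) integer class of the source cell
    same_type: np.ndarray  # (size,) bool
    source_batch: str
    target_batch: str
    source_ids: np.ndarray | None = None  # cell ids, for debugging/dumps
    target_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.x_source)
        if not (len(self.x_target) == len(self.y_source) == len(self.same_type) == n):
            raise ValueError("pair batch arrays must have equal length")

    @property
    def size(self) -> int:
        return len(self.x_source)


@dataclass
class PairSchedule:
    """Rotation order of (source, target) batch pairs for training.

    One cycle enumerates all ordered pairs of distinct batches before
    repeating, so every batch serves as the source domain.
    """

    steps: list[tuple[str, str]]
    seed: int = 0

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def step(self, i: int) -> tuple[str, str]:
        """The i-th training step's (source, target) pair, cycling forever."""
        return self.steps[i % len(self.steps)]


@dataclass
class Embedding:
    """Integrated low-dimensional coordinates for all cells."""

    coords: np.ndarray  # (n_cells, d)
    cell_ids: np.ndarray
    cell_types: np.ndarray
    batch_ids: np.ndarray  # per-cell batch id

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        self.batch_ids = np.asarray(self.batch_ids, dtype=object)
        n = len(self.coords)
        if not (len(self.cell_ids) == len(self.cell_types) == len(self.batch_ids) == n):
            raise ValueError("embedding annotation arrays must match row count")
        if n and not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return len(self.coords)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "batch_id": self.batch_ids,
                "cell_type": self.cell_types,
            }
        )
        for j in range(self.dim):
            df[f"dim{j}"] = self.coords[:, j]
        return df

    def subset(self, mask: np.ndarray) -> "Embedding":
        return Embedding(
            self.coords[mask],
            self.cell_ids[mask],
            self.cell_types[mask],
            self.batch_ids[mask],
        )
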