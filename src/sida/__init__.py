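"""SIDA: supervised integration of multi-batch scRNA-seq data.

A Siamese domain-adaptation network trained with a classification +
contrastive semantic alignment objective learns a shared embedding in which
batches are mixed and cell types separated, guided by per-cell annotations.
The package also ships the six-metric integration evaluation suite
(positive/true-positive rate, kBET, LISI, ASW, ARI harmonic-mean scores),
MNN-anchor back-projection of the embedding to gene space, leave-one-batch-
out cell-type mapping, and a synthetic-data generator with ground truth.
"""

from .datatypes import (
    DataCollection,
    Embedding,
    ExpressionBatch,
    PairBatch,
    PairSchedule,
    PCView,
)
from .io import (
    consolidate_labels,
    read_collection,
    read_embedding,
    write_collection,
    write_embedding,
)
from .metrics import MetricsReport, evaluate_all
from .model import (
    SidaConfig,
    SidaIntegrator,
    classification_loss,
    embed,
    load_model,
    save_model,
    semantic_alignment_loss,
    separation_loss,
    total_loss,
    train,
)
from .pairs import draw_pair_batch, make_schedule, subsample_cells
from .preprocess import intersect_genes, normalize_log, pca_per_batch, preprocess_collection
from .reference import (
    AnchorSet,
    CellTypeMapper,
    ReferencePanel,
    find_anchors,
    leave_one_out,
    map_cell_types,
    project_to_gene_space,
)
from .simulate import SimConfig, shifted_twin_collection, simulate_collection, smoke_fixture

__version__ = "0.1.0"

__all__ = [
    "DataCollection",
    "Embedding",
    "ExpressionBatch",
    "PairBatch",
    "PairSchedule",
    "PCView",
    "consolidate_labels",
    "read_collection",
    "read_embedding",
    "write_collection",
    "write_embedding",
    "MetricsReport",
    "evaluate_all",
    "SidaConfig",
    "SidaIntegrator",
    "classification_loss",
    "semantic_alignment_loss",
    "separation_loss",
    "total_loss",
    "train",
    "embed",
    "save_model",
    "load_model",
    "draw_pair_batch",
    "make_schedule",
    "subsample_cells",
    "intersect_genes",
    "normalize_log",
    "pca_per_batch",
    "preprocess_collection",
    "AnchorSet",
    "CellTypeMapper",
    "ReferencePanel",
    "find_anchors",
    "leave_one_out",
    "map_cell_types",
    "project_to_gene_space",
    "SimConfig",
    "shifted_twin_collection",
    "simulate_collection",
    "smoke_fixture",
    "integrate_collection",
]


def integrate_collection(collection, config=None, n_pcs: int = 50):
    """End-to-end convenience: preprocess, train, embed.

    Returns ``(model, embedding, pc_view)``.
    """
    from .model import SidaConfig, embed, train
    from .preprocess import preprocess_collection

    config = config or SidaConfig()
    _, view = preprocess_collection(collection, n_pcs=n_pcs)
    model = train(view, config=config)
    return model, embed(model, view), view
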