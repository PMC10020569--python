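import numpy as np
import pytest

from sida.datatypes import DataCollection, Embedding, ExpressionBatch
from sida.simulate import SimConfig, simulate_collection


def make_batch(
    rng: np.random.Generator,
    batch_id: str = "b0",
    n_cells: int = 20,
    genes: list[str] | None = None,
    types: list[str] | None = None,
) -> ExpressionBatch:
    genes = genes if genes is not None else [f"g{i}" for i in range(8)]
    types = types if types is not None else ["alpha", "beta"]
    return ExpressionBatch(
        matrix=rng.poisson(5.0, size=(n_cells, len(genes))).astype(float),
        gene_names=np.array(genes, dtype=object),
        cell_ids=np.array([f"{batch_id}_c{i}" for i in range(n_cells)], dtype=object),
        cell_types=np.array([types[i % len(types)] for i in range(n_cells)], dtype=object),
        batch_id=batch_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_collection(rng) -> DataCollection:
    """Three tiny random batches sharing a gene set."""
    return DataCollection([make_batch(rng, f"b{i}", n_cells=15 + i) for i in range(3)])


@pytest.fixture
def random_embedding(rng) -> Embedding:
    """200 random cells, 2 types, 2 batches, 5-dim coordinates."""
    n = 200
    return Embedding(
        coords=rng.normal(size=(n, 5)),
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        cell_types=np.array(["t" + str(i % 2) for i in range(n)], dtype=object),
        batch_ids=np.array(["b" + str((i // 2) % 2) for i in range(n)], dtype=object),
    )


@pytest.fixture(scope="session")
def sim_tiny():
    """Deterministic tiny simulated collection with known truth."""
    cfg = SimConfig(
        n_batches=2,
        n_shared_types=3,
        n_batch_specific=0,
        cells_per_type=60,
        n_genes=120,
        batch_effect="shift",
        seed=7,
    )
    return simulate_collection(cfg)
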