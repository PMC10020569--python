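"""Synthetic multi-batch scRNA-seq collections with known ground truth.

The generator emulates the structural features the integration pipeline has
to cope with: several batches over a shared gene set, cell types as
well-separated Gaussian clusters in log-expression space, per-batch
affine/offset batch effects, batch-specific cell types, and (optionally)
inconsistent annotation vocabularies that exercise label consolidation.

Geometry: each cell type's mean sits at ``base_expression`` plus a scaled
orthonormal direction, so any two type means are exactly
``effect_size * noise_sd`` apart -- one knob controls separability.
Batch-effect shift vectors have nonnegative entries, which keeps the shift
exactly invertible despite the clip of log-expression values at zero.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .datatypes import DataCollection, ExpressionBatch

__all__ = ["SimConfig", "simulate_collection", "smoke_fixture", "shifted_twin_collection"]

# spelling variants used when vocab_noise is on; index = batch position mod 4
_VARIANTS = [
    lambda t: t,
    lambda t: t.upper(),
    lambda t: t + " cells",
    lambda t: t.capitalize() + "s",
]


@dataclass
class SimConfig:
    """Generator settings.

    ``effect_size`` is the distance between any two type means in units of
    the within-type standard deviation; ``batch_magnitude`` is the norm of
    the per-batch shift in the same units.  ``count_model='gaussian-log'``
    emits values already on log scale (matching the post-log pipeline);
    ``'negative-binomial'`` emits raw counts to exercise normalization.
    """

    n_batches: int = 3
    n_shared_types: int = 5
    n_batch_specific: int = 1
    cells_per_type: int = 200
    n_genes: int = 500
    effect_size: float = 4.0
    batch_effect: str = "shift"  # 'shift' | 'affine' | 'none'
    batch_magnitude: float = 6.0
    affine_gamma: float = 0.15
    count_model: str = "gaussian-log"  # or 'negative-binomial'
    dispersion: float = 2.0
    vocab_noise: bool = False
    base_expression: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.n_genes < 1 or self.cells_per_type < 1:
            raise ValueError("sizes must be positive")
        if self.batch_magnitude < 0 or self.effect_size < 0:
            raise ValueError("magnitudes must be >= 0")
        if self.n_shared_types < 1 and self.n_batches >= 2:
            raise ValueError("need >= 1 shared type across batches")
        if self.batch_effect not in ("shift", "affine", "none"):
            raise ValueError(f"unknown batch_effect {self.batch_effect!r}")
        if self.count_model not in ("gaussian-log", "negative-binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        n_types = self.n_shared_types + self.n_batch_specific
        if n_types > self.n_genes:
            raise ValueError("need n_genes >= number of types for orthogonal means")


def _type_layout(config: SimConfig) -> dict[str, list[str]]:
    """Which types appear in which batch; batch-specific ones round-robin."""
    shared = [f"type{i}" for i in range(config.n_shared_types)]
    layout = {f"batch{b}": list(shared) for b in range(config.n_batches)}
    for j in range(config.n_batch_specific):
        b = j % config.n_batches
        layout[f"batch{b}"].append(f"type{config.n_shared_types + j}")
    return layout


def simulate_collection(config: SimConfig) -> tuple[DataCollection, dict]:
    """Generate a collection plus a ground-truth record.

    The truth record holds the type means, per-batch transforms, the correct
    ``label_map`` (identity unless ``vocab_noise``), and the config -- so
    recovery tests need no external reference.
    """
    rng = np.random.default_rng(config.seed)
    layout = _type_layout(config)
    all_types = sorted({t for ts in layout.values() for t in ts})
    G = config.n_genes

    # orthonormal type directions -> exact pairwise mean separation
    Q, _ = np.linalg.qr(rng.standard_normal((G, len(all_types))))
    scale = config.effect_size * config.noise_sd / np.sqrt(2.0)
    means = {t: config.base_expression + scale * Q[:, i] for i, t in enumerate(all_types)}

    shifts: dict[str, np.ndarray] = {}
    affines: dict[str, np.ndarray] = {}
    batches = []
    label_map: dict[str, str] = {}
    for bi, (bid, types) in enumerate(layout.items()):
        rows, labels = [], []
        for t in types:
            X = means[t][None, :] + config.noise_sd * rng.standard_normal(
                (config.cells_per_type, G)
            )
            rows.append(X)
            labels.extend([t] * config.cells_per_type)
        X = np.vstack(rows)

        A = np.eye(G)
        v = np.zeros(G)
        if bi > 0 and config.batch_effect != "none":
            direction = np.abs(rng.standard_normal(G))
            v = config.batch_magnitude * config.noise_sd * direction / np.linalg.norm(direction)
            if config.batch_effect == "affine":
                A = np.eye(G) + config.affine_gamma * rng.standard_normal((G, G)) / np.sqrt(G)
                A *= 1.0 + 0.05 * rng.standard_normal(G)[None, :]
            X = X @ A.T
        X = X + v
        shifts[bid] = v
        affines[bid] = A

        X = np.clip(X, 0.0, None)
        if config.count_model == "negative-binomial":
            mu = np.expm1(X)
            lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
            X = rng.poisson(lam).astype(float)

        variant = _VARIANTS[bi % len(_VARIANTS)] if config.vocab_noise else _VARIANTS[0]
        noisy = [variant(t) for t in labels]
        for raw, canon in zip(noisy, labels):
            label_map[raw] = canon

        batches.append(
            ExpressionBatch(
                matrix=X,
                gene_names=np.array([f"gene{g}" for g in range(G)], dtype=object),
                cell_ids=np.array([f"{bid}_cell{i}" for i in range(len(X))], dtype=object),
                cell_types=np.array(noisy, dtype=object),
                batch_id=bid,
            )
        )

    collection = DataCollection(batches, is_log=config.count_model == "gaussian-log")
    truth = {
        "config": asdict(config),
        "layout": layout,
        "type_means": means,
        "shifts": shifts,
        "affines": affines,
        "label_map": label_map,
    }
    return collection, truth


def smoke_fixture(scale: str = "tiny", seed: int = 0, **overrides) -> DataCollection:
    """Ready-made collections for end-to-end runs.

    ``tiny``: 2 batches x 3 shared types x 60 cells x 120 genes, shift batch
    effect -- the whole integrate+evaluate pipeline finishes in well under
    two minutes.  ``small``: 3 batches x 6 types (one batch-specific) x 200
    cells x 500 genes with a strong affine+shift batch effect.
    """
    if scale == "tiny":
        cfg = SimConfig(
            n_batches=2,
            n_shared_types=3,
            n_batch_specific=0,
            cells_per_type=60,
            n_genes=120,
            batch_effect="shift",
            seed=seed,
        )
    elif scale == "small":
        cfg = SimConfig(
            n_batches=3,
            n_shared_types=5,
            n_batch_specific=1,
            cells_per_type=200,
            n_genes=500,
            batch_effect="affine",
            seed=seed,
        )
    elif scale == "pancreas-like":
        # 4 types in every batch plus 4 batch-specific ones, 5 batches
        cfg = SimConfig(
            n_batches=5,
            n_shared_types=4,
            n_batch_specific=4,
            cells_per_type=100,
            n_genes=400,
            batch_effect="affine",
            vocab_noise=True,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown scale {scale!r}")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.__post_init__()
    collection, _ = simulate_collection(cfg)
    return collection


def shifted_twin_collection(
    n_cells: int = 150,
    n_genes: int = 100,
    n_types: int = 3,
    shift_magnitude: float = 5.0,
    seed: int = 0,
) -> tuple[DataCollection, np.ndarray]:
    """Two batches where batch1 is an exact cell-by-cell shifted copy of batch0.

    Returns the collection and the shift vector ``delta`` (nonnegative
    entries, so clipping never touches it).  Used to test exact recovery of
    an additive batch effect by anchor-based gene-space correction.
    """
    base, truth = simulate_collection(
        SimConfig(
            n_batches=1,
            n_shared_types=n_types,
            n_batch_specific=0,
            cells_per_type=max(1, n_cells // n_types),
            n_genes=n_genes,
            batch_effect="none",
            seed=seed,
        )
    )
    b0 = base.batches[0]
    rng = np.random.default_rng(seed + 1)
    direction = np.abs(rng.standard_normal(n_genes))
    delta = shift_magnitude * direction / np.linalg.norm(direction)
    b1 = ExpressionBatch(
        matrix=b0.matrix + delta,
        gene_names=b0.gene_names.copy(),
        cell_ids=np.array([f"twin_{c}" for c in b0.cell_ids], dtype=object),
        cell_types=b0.cell_types.copy(),
        batch_id="batch1",
    )
    return DataCollection([b0, b1], is_log=True), delta
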