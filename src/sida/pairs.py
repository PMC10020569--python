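"""Training-pair generation for the Siamese network.

Cells are first subsampled per (batch, cell type) so abundant types do not
dominate; training pairs are then drawn from ordered batch pairs "in a
rotated fashion" -- for batches 1..n one cycle visits (1,2), (1,3), ...,
(n-1,n), then the reversed pairs, so every batch serves as the source domain
and the classifier sees every batch's types (including batch-specific ones).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np

from .datatypes import PairBatch, PairSchedule, PCView

__all__ = ["subsample_cells", "make_schedule", "draw_pair_batch"]


def subsample_cells(pc_view: PCView, cells_per_type: int, seed: int = 0) -> PCView:
    """Keep at most ``cells_per_type`` cells per (batch, cell type).

    Sampling is without replacement and deterministic given ``seed``; a
    type with fewer cells keeps them all.
    """
    if cells_per_type < 1:
        raise ValueError("cells_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    coords, cids, ctypes = [], [], []
    for bi in range(pc_view.n_batches):
        types = pc_view.cell_types[bi]
        keep: list[np.ndarray] = []
        for t in sorted(set(types)):
            idx = np.flatnonzero(types == t)
            if len(idx) > cells_per_type:
                idx = rng.choice(idx, size=cells_per_type, replace=False)
            keep.append(np.sort(idx))
        sel = np.concatenate(keep)
        coords.append(pc_view.coords[bi][sel])
        cids.append(pc_view.cell_ids[bi][sel])
        ctypes.append(types[sel])
    return PCView(
        coords=coords,
        cell_ids=cids,
        cell_types=ctypes,
        batch_ids=list(pc_view.batch_ids),
        n_pcs=pc_view.n_pcs,
    )


def make_schedule(batch_ids: list[str], seed: int = 0) -> PairSchedule:
    """One rotation cycle over all ordered pairs of distinct batches.

    The cycle lists every unordered pair with its first element as source,
    then the same pairs reversed: for {1,2,3} this is
    (1,2), (1,3), (2,3), (2,1), (3,1), (3,2).  Training repeats the cycle.
    """
    if len(batch_ids) < 2:
        raise ValueError("need >= 2 batches to integrate")
    forward = list(combinations(batch_ids, 2))
    steps = forward + [(b, a) for a, b in forward]
    return PairSchedule(steps=steps, seed=seed)


def draw_pair_batch(
    pc_view: PCView,
    step: tuple[str, str],
    size: int,
    pos_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> PairBatch:
    """Draw ``size`` (source cell, target cell) pairs for one schedule step.

    Positive (same cell type) pairs make up round(size * pos_fraction) of the
    batch when both kinds are available; sampling is stratified by type (pick
    a type, then cells within it) so rare types stay represented.  Types
    present only in the source batch appear in negative pairs and in the
    classification labels ``y_source``, never in positive pairs.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    src_i = pc_view.batch_index(step[0])
    tgt_i = pc_view.batch_index(step[1])
    Xs_all, Xt_all = pc_view.coords[src_i], pc_view.coords[tgt_i]
    ts_all, tt_all = pc_view.cell_types[src_i], pc_view.cell_types[tgt_i]
    if len(Xs_all) == 0 or len(Xt_all) == 0:
        raise ValueError("empty batch in pair step")

    universe = sorted(set(np.concatenate(pc_view.cell_types)))
    class_of = {t: i for i, t in enumerate(universe)}

    src_types = sorted(set(ts_all))
    tgt_types = sorted(set(tt_all))
    shared = [t for t in src_types if t in set(tgt_types)]
    src_idx = {t: np.flatnonzero(ts_all == t) for t in src_types}
    tgt_idx = {t: np.flatnonzero(tt_all == t) for t in tgt_types}

    n_pos = int(round(size * pos_fraction))
    # negative pairs need either >=2 types overall or disjoint vocabularies
    can_neg = len(src_types) > 1 or len(tgt_types) > 1 or set(src_types) != set(tgt_types)
    if not shared and n_pos > 0:
        warnings.warn(
            f"no shared cell types between {step[0]!r} and {step[1]!r}; "
            "emitting only negative pairs"
        )
        n_pos = 0
    if not can_neg:
        n_pos = size
    n_neg = size - n_pos

    s_rows, t_rows, flags = [], [], []
    if n_pos:
        types = rng.choice(shared, size=n_pos)
        for t in types:
            s_rows.append(rng.choice(src_idx[t]))
            t_rows.append(rng.choice(tgt_idx[t]))
            flags.append(True)
    drawn = 0
    while drawn < n_neg:
        ts = rng.choice(src_types)
        diff = [t for t in tgt_types if t != ts]
        if not diff:
            continue
        tt = rng.choice(diff)
        s_rows.append(rng.choice(src_idx[ts]))
        t_rows.append(rng.choice(tgt_idx[tt]))
        flags.append(False)
        drawn += 1

    s_rows = np.array(s_rows, dtype=int)
    t_rows = np.array(t_rows, dtype=int)
    return PairBatch(
        x_source=Xs_all[s_rows],
        x_target=Xt_all[t_rows],
        y_source=np.array([class_of[t] for t in ts_all[s_rows]], dtype=int),
        same_type=np.array(flags, dtype=bool),
        source_batch=step[0],
        target_batch=step[1],
        source_ids=pc_view.cell_ids[src_i][s_rows],
        target_ids=pc_view.cell_ids[tgt_i][t_rows],
    )


def dump_pairs(
    pc_view: PCView,
    schedule,
    path,
    size: int = 64,
    pos_fraction: float = 0.5,
    seed: int = 0,
) -> None:
    """Debug dump: one schedule cycle of pairs as (source_id, target_id,
    same_type) TSV."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for step in schedule:
        pb = draw_pair_batch(pc_view, step, size, pos_fraction=pos_fraction, rng=rng)
        for s, t, f in zip(pb.source_ids, pb.target_ids, pb.same_type):
            rows.append((s, t, bool(f)))
    pd.DataFrame(rows, columns=["source_id", "target_id", "same_type"]).to_csv(
        path, sep="\t", index=False
    )
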