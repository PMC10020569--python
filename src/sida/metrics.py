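"""Six integration-quality metrics: kNN positive/true-positive rate, kBET,
LISI F1, ASW F1, ARI F1.

All metrics are computed on an integrated embedding with per-cell cell-type
and batch annotations.  Mixing metrics (kBET, iLISI, ASW_batch, ARI_batch)
reward neighborhoods whose batch composition matches the global one;
separation metrics (positive rate, cLISI, ASW_celltype, ARI_celltype)
reward type-pure, well-separated neighborhoods.  Each paired metric is
combined into a single score by the harmonic-mean F1 form
``2*(1-mixing_bad)(separation_good)/((1-mixing_bad)+separation_good)``.

kNN conventions used throughout: Euclidean distance, the cell itself is
excluded, and ties are broken by (stable) cell index so results are exactly
reproducible and brute-force checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .datatypes import Embedding

__all__ = [
    "MetricsReport",
    "knn_indices",
    "positive_rate",
    "true_positive_rate",
    "kbet",
    "lisi",
    "f1_lisi",
    "asw",
    "f1_asw",
    "ari",
    "evaluate_all",
]


def knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of each cell's k nearest neighbors (self excluded).

    Stable argsort on distances breaks ties by cell index.  Brute force by
    design: at the problem sizes this package evaluates (thousands of
    cells), exactness and reproducibility beat an index structure.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(coords)
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    sq = np.sum(coords**2, axis=1)
    out = np.empty((n, k), dtype=int)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] - 2.0 * coords[start:stop] @ coords.T + sq[None, :]
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        # round-off guard: exact ties must compare equal for stable ordering
        d2 = np.round(d2, 9)
        out[start:stop] = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return out


def positive_rate(
    coords: np.ndarray,
    cell_types: np.ndarray,
    k: int = 50,
    purity: float = 0.95,
    knn: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Fraction of cells with a type-pure neighborhood.

    A cell is 'positive' when at least ``purity`` (default 95%) of its
    ``k`` (default 50) nearest neighbors carry its own cell-type label.
    Returns the rate and the per-cell positive flags.
    """
    cell_types = np.asarray(cell_types, dtype=object)
    if knn is None:
        knn = knn_indices(coords, k)
    same = cell_types[knn] == cell_types[:, None]
    flags = same.mean(axis=1) >= purity
    return float(flags.mean()), flags


def true_positive_rate(
    coords: np.ndarray,
    cell_types: np.ndarray,
    batch_ids: np.ndarray,
    positive_flags: np.ndarray,
    k: int = 50,
    knn: np.ndarray | None = None,
) -> float:
    """Fraction of cells that are positive AND batch-mixed per the 3-sigma rule.

    For a positive cell of type t, let ``p_i = N_i / sum_j N_j`` be the share
    of type-t cells contributed by batch i.  The cell is a true positive when
    its neighbor count from every batch i lies in
    ``[max(0, k*p_i - 3*sqrt(k*p_i*(1-p_i))), k*p_i + 3*sqrt(k*p_i*(1-p_i))]``.
    The denominator is all cells, so true_positive_rate <= positive_rate.
    """
    cell_types = np.asarray(cell_types, dtype=object)
    batch_ids = np.asarray(batch_ids, dtype=object)
    if knn is None:
        knn = knn_indices(coords, k)
    batches = sorted(set(batch_ids.tolist()))
    b_index = {b: i for i, b in enumerate(batches)}
    b_codes = np.array([b_index[b] for b in batch_ids])
    n_true = 0
    for i in np.flatnonzero(positive_flags):
        t = cell_types[i]
        of_type = cell_types == t
        N = np.bincount(b_codes[of_type], minlength=len(batches)).astype(float)
        p = N / N.sum()
        M = np.bincount(b_codes[knn[i]], minlength=len(batches)).astype(float)
        sd = 3.0 * np.sqrt(k * p * (1.0 - p))
        lo = np.maximum(0.0, k * p - sd)
        hi = k * p + sd
        if np.all((M >= lo) & (M <= hi)):
            n_true += 1
    return n_true / len(coords)


def _kbet_chi2(observed: np.ndarray, expected: np.ndarray) -> float:
    """Pearson goodness-of-fit statistic over batch categories.

    Categories with zero expected count (a batch absent from the data set)
    are dropped before summing.
    """
    keep = expected > 0
    o, e = observed[keep], expected[keep]
    return float(np.sum((o - e) ** 2 / e))


def kbet(
    coords: np.ndarray,
    batch_ids: np.ndarray,
    k: int = 50,
    sample_fraction: float = 0.10,
    alpha: float = 0.05,
    seed: int = 0,
    knn: np.ndarray | None = None,
) -> float:
    """k-nearest-neighbor batch-effect test score, 1 - rejection rate.

    A seeded ``sample_fraction`` of the cells is tested: each sampled
    cell's kNN batch composition is compared against the global batch
    proportions with a Pearson chi-square test (df = n_batches - 1, no
    continuity correction); the score is the fraction NOT rejected at level
    ``alpha``.  Close to 1 means batches are well mixed locally.
    """
    batch_ids = np.asarray(batch_ids, dtype=object)
    n = len(coords)
    batches = sorted(set(batch_ids.tolist()))
    if len(batches) < 2:
        raise ValueError("kBET needs >= 2 batches")
    n_sample = max(1, int(round(n * sample_fraction)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_sample, replace=False)
    if knn is None:
        knn = knn_indices(coords, k)
    b_index = {b: i for i, b in enumerate(batches)}
    b_codes = np.array([b_index[b] for b in batch_ids])
    global_p = np.bincount(b_codes, minlength=len(batches)) / n
    crit = scipy.stats.chi2.ppf(1.0 - alpha, df=len(batches) - 1)
    rejected = 0
    for i in chosen:
        obs = np.bincount(b_codes[knn[i]], minlength=len(batches)).astype(float)
        stat = _kbet_chi2(obs, k * global_p)
        if stat > crit:
            rejected += 1
    return 1.0 - rejected / n_sample


def lisi(
    coords: np.ndarray,
    labels: np.ndarray,
    perplexity: float = 30.0,
    tol: float = 1e-5,
) -> np.ndarray:
    """Per-cell local inverse Simpson's index of ``labels`` diversity.

    Neighbor weights use a Gaussian kernel whose bandwidth is calibrated per
    cell by bisection so the weight distribution has the fixed perplexity
    (as in t-SNE); category probabilities p(b) are the weighted neighbor
    label composition and the score is ``1 / sum_b p(b)^2``, ranging from 1
    (one category) to B (uniform over B categories).
    """
    labels = np.asarray(labels, dtype=object)
    n = len(coords)
    if perplexity >= n:
        raise ValueError("perplexity must be < number of cells")
    cats = sorted(set(labels.tolist()))
    codes = np.array([cats.index(l) for l in labels])
    nn = min(n - 1, max(int(np.ceil(3 * perplexity)), 5))
    knn = knn_indices(coords, nn)
    target_h = np.log(perplexity)
    scores = np.empty(n)
    for i in range(n):
        dist2 = np.sum((coords[knn[i]] - coords[i]) ** 2, axis=1)
        beta_lo, beta_hi, beta = 0.0, np.inf, 1.0
        for _ in range(64):
            w = np.exp(-beta * dist2)
            s = w.sum()
            if s <= 0:
                h = 0.0
                p = np.zeros_like(w)
            else:
                p = w / s
                with np.errstate(divide="ignore", invalid="ignore"):
                    h = float(-np.sum(p * np.log(np.where(p > 0, p, 1.0))))
            if abs(h - target_h) < tol:
                break
            if h > target_h:
                beta_lo = beta
                beta = beta * 2 if beta_hi == np.inf else (beta_lo + beta_hi) / 2
            else:
                beta_hi = beta
                beta = (beta_lo + beta_hi) / 2
        pb = np.bincount(codes[knn[i]], weights=p, minlength=len(cats))
        simpson = float(np.sum(pb**2))
        scores[i] = 1.0 / simpson if simpson > 0 else 1.0
    return scores


def f1_lisi(ilisi_rescaled: float, clisi_rescaled: float) -> float:
    """Harmonic-mean combination of rescaled iLISI (batch mixing, higher
    better) and cLISI (cell-type mixing, lower better), both in [0, 1]."""
    num = 2.0 * (1.0 - clisi_rescaled) * ilisi_rescaled
    den = (1.0 - clisi_rescaled) + ilisi_rescaled
    return num / den if den > 0 else 0.0


def asw(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width of ``labels`` in the embedding (raw, in [-1,1])."""
    labels = np.asarray(labels, dtype=object).astype(str)
    if len(set(labels)) < 2:
        raise ValueError("silhouette needs >= 2 distinct labels")
    return float(np.mean(silhouette_samples(coords, labels, metric="euclidean")))


def f1_asw(asw_batch_rescaled: float, asw_celltype_rescaled: float) -> float:
    """Harmonic-mean combination of rescaled ASW scores (both in [0, 1])."""
    num = 2.0 * (1.0 - asw_batch_rescaled) * asw_celltype_rescaled
    den = (1.0 - asw_batch_rescaled) + asw_celltype_rescaled
    return num / den if den > 0 else 0.0


def ari(
    coords: np.ndarray,
    cell_type_labels: np.ndarray,
    batch_labels: np.ndarray,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[float, float, float]:
    """k-means (k = number of cell types) ARI agreement scores.

    Returns ``(f1_ari, ari_celltype, ari_batch)``; each ARI is clamped at 0
    before the harmonic-mean combination (chance-level ARI can be slightly
    negative).
    """
    cell_type_labels = np.asarray(cell_type_labels, dtype=object).astype(str)
    batch_labels = np.asarray(batch_labels, dtype=object).astype(str)
    C = len(set(cell_type_labels))
    if C < 2:
        raise ValueError("ARI needs >= 2 cell types")
    if len(coords) < C:
        raise ValueError("fewer cells than cell types")
    km = KMeans(n_clusters=C, n_init=n_restarts, random_state=seed)
    pred = km.fit_predict(coords)
    ari_ct = max(0.0, adjusted_rand_score(cell_type_labels, pred))
    ari_b = max(0.0, adjusted_rand_score(batch_labels, pred))
    num = 2.0 * (1.0 - ari_b) * ari_ct
    den = (1.0 - ari_b) + ari_ct
    return (num / den if den > 0 else 0.0), ari_ct, ari_b


@dataclass
class MetricsReport:
    """The six headline integration scores plus sub-scores and parameters."""

    positive_rate: float
    true_positive_rate: float
    kbet: float
    f1_lisi: float
    f1_asw: float
    f1_ari: float
    subscores: dict[str, float] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=dict)

    def headline(self) -> dict[str, float]:
        return {
            "positive_rate": self.positive_rate,
            "true_positive_rate": self.true_positive_rate,
            "kbet": self.kbet,
            "f1_lisi": self.f1_lisi,
            "f1_asw": self.f1_asw,
            "f1_ari": self.f1_ari,
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([self.headline()])


def evaluate_all(
    embedding: Embedding,
    k: int = 50,
    purity: float = 0.95,
    perplexity: float = 30.0,
    sample_fraction: float = 0.10,
    alpha: float = 0.05,
    seed: int = 0,
) -> MetricsReport:
    """Compute all six metrics on one embedding; deterministic given ``seed``."""
    coords = embedding.coords
    types = embedding.cell_types
    batches = embedding.batch_ids
    knn = knn_indices(coords, k)

    pr, flags = positive_rate(coords, types, k=k, purity=purity, knn=knn)
    tpr = true_positive_rate(coords, types, batches, flags, k=k, knn=knn)
    kb = kbet(
        coords, batches, k=k, sample_fraction=sample_fraction, alpha=alpha, seed=seed, knn=knn
    )

    n_b = len(set(batches.tolist()))
    n_t = len(set(types.tolist()))
    if n_b < 2:
        raise ValueError("iLISI needs >= 2 batches")
    ilisi_raw = float(np.mean(lisi(coords, batches, perplexity=perplexity)))
    clisi_raw = float(np.mean(lisi(coords, types, perplexity=perplexity)))
    ilisi = (ilisi_raw - 1.0) / (n_b - 1.0)
    clisi = (clisi_raw - 1.0) / (n_t - 1.0) if n_t > 1 else 0.0
    f1l = f1_lisi(ilisi, clisi)

    asw_ct_raw = asw(coords, types)
    asw_b_raw = asw(coords, batches)
    f1a = f1_asw((asw_b_raw + 1.0) / 2.0, (asw_ct_raw + 1.0) / 2.0)

    f1r, ari_ct, ari_b = ari(coords, types, batches, seed=seed)

    return MetricsReport(
        positive_rate=pr,
        true_positive_rate=tpr,
        kbet=kb,
        f1_lisi=f1l,
        f1_asw=f1a,
        f1_ari=f1r,
        subscores={
            "ilisi_raw": ilisi_raw,
            "clisi_raw": clisi_raw,
            "ilisi": ilisi,
            "clisi": clisi,
            "asw_batch_raw": asw_b_raw,
            "asw_celltype_raw": asw_ct_raw,
            "ari_batch": ari_b,
            "ari_celltype": ari_ct,
        },
        params={
            "k": k,
            "purity": purity,
            "perplexity": perplexity,
            "sample_fraction": sample_fraction,
            "alpha": alpha,
            "seed": seed,
        },
    )
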