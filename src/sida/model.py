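"""Siamese domain-adaptation network and its training objective.

Architecture
------------
A weight-shared feature branch ``g`` maps each cell's per-batch PC vector
into a common space; a two-layer feed-forward classifier ``h`` (plus a
linear softmax head) sits on top of the source branch.  The integrated
embedding is the output of the second feature layer of ``h``.

The objective is the classification + contrastive semantic alignment (CCSA)
loss: same-type cross-batch pairs are pulled together (semantic alignment),
different-type pairs are pushed beyond a margin ``m`` (separation), and a
cross-entropy term trains the classifier — which also covers cell types
unique to a single batch, since the rotated pair schedule makes every batch
the source domain in turn.

The network is implemented directly in numpy (see :mod:`sida.nn`): the
model is small (50-dimensional input, a few thousand parameters), so exact,
dependency-free, bit-reproducible training on a CPU is preferable to a
heavyweight framework.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import Embedding, PairBatch, PairSchedule, PCView
from .nn import Adam, Conv1d, Dense, Flatten, ReLU, Sequential

__all__ = [
    "SidaConfig",
    "SidaIntegrator",
    "semantic_alignment_loss",
    "separation_loss",
    "classification_loss",
    "total_loss",
    "train",
    "embed",
    "save_model",
    "load_model",
]

_EPS = 1e-12


@dataclass
class SidaConfig:
    """Hyperparameters of the integration network.

    ``margin`` is the separation margin ``m``; ``sa_squared`` switches the
    alignment term between half the squared Euclidean distance (the classic
    contrastive form, default) and half the plain distance.
    """

    margin: float = 1.0
    alpha_sa: float = 1.0
    alpha_s: float = 1.0
    alpha_c: float = 1.0
    n_steps: int = 3000
    lr: float = 3e-3
    batch_size: int = 64
    embedding_dim: int = 64
    g_out: int = 64
    g_channels: tuple[int, int] = (16, 32)
    kernel: int = 3
    h_hidden: int = 128
    arch: str = "conv"  # 'conv' or 'mlp'
    sa_squared: bool = True
    pos_fraction: float = 0.5
    cells_per_type: int = 400
    lr_decay: float = 0.1  # final lr = lr * lr_decay (linear schedule); 1.0 = constant
    patience: int | None = None  # early stop after this many non-improving cycles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if min(self.alpha_sa, self.alpha_s, self.alpha_c) < 0 or (
            self.alpha_sa + self.alpha_s + self.alpha_c == 0
        ):
            raise ValueError("loss weights must be >= 0 with at least one > 0")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")


# ---------------------------------------------------------------------------
# loss components (public scalar forms + internal gradient forms)


def _pair_distances(g_s: np.ndarray, g_t: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum((g_s - g_t) ** 2, axis=1))


def semantic_alignment_loss(
    g_s: np.ndarray, g_t: np.ndarray, same_type: np.ndarray, sa_squared: bool = False
) -> float:
    """Mean over same-type pairs of half the (optionally squared) distance."""
    pos = np.asarray(same_type, dtype=bool)
    if not pos.any():
        warnings.warn("no positive pairs; semantic alignment loss is 0")
        return 0.0
    d = _pair_distances(g_s[pos], g_t[pos])
    return float(np.mean(0.5 * (d**2 if sa_squared else d)))


def separation_loss(
    g_s: np.ndarray, g_t: np.ndarray, same_type: np.ndarray, m: float
) -> float:
    """Mean over different-type pairs of the squared hinge 0.5*max(0, m-d)^2."""
    if m <= 0:
        raise ValueError("margin must be > 0")
    neg = ~np.asarray(same_type, dtype=bool)
    if not neg.any():
        warnings.warn("no negative pairs; separation loss is 0")
        return 0.0
    d = _pair_distances(g_s[neg], g_t[neg])
    return float(np.mean(0.5 * np.maximum(0.0, m - d) ** 2))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def classification_loss(logits: np.ndarray, y_source: np.ndarray) -> float:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    y = np.asarray(y_source, dtype=int)
    C = logits.shape[1]
    if y.min(initial=0) < 0 or y.max(initial=0) >= C:
        raise ValueError(f"labels must lie in [0, {C})")
    p = _softmax(logits)
    return float(-np.mean(np.log(p[np.arange(len(y)), y] + _EPS)))


def _sa_grads(g_s, g_t, same_type, sa_squared):
    """(loss, d/dg_s, d/dg_t) of the semantic alignment term."""
    pos = np.asarray(same_type, dtype=bool)
    ds = np.zeros_like(g_s)
    dt = np.zeros_like(g_t)
    if not pos.any():
        return 0.0, ds, dt
    diff = g_s[pos] - g_t[pos]
    d = np.sqrt(np.sum(diff**2, axis=1))
    n = pos.sum()
    if sa_squared:
        loss = float(np.mean(0.5 * d**2))
        g = diff / n
    else:
        loss = float(np.mean(0.5 * d))
        g = 0.5 * diff / (np.maximum(d, _EPS)[:, None] * n)
    ds[pos] = g
    dt[pos] = -g
    return loss, ds, dt


def _sep_grads(g_s, g_t, same_type, m):
    neg = ~np.asarray(same_type, dtype=bool)
    ds = np.zeros_like(g_s)
    dt = np.zeros_like(g_t)
    if not neg.any():
        return 0.0, ds, dt
    diff = g_s[neg] - g_t[neg]
    d = np.sqrt(np.sum(diff**2, axis=1))
    hinge = np.maximum(0.0, m - d)
    n = neg.sum()
    loss = float(np.mean(0.5 * hinge**2))
    g = (-hinge / np.maximum(d, _EPS))[:, None] * diff / n
    ds[neg] = g
    dt[neg] = -g
    return loss, ds, dt


def _ce_grads(logits, y):
    p = _softmax(logits)
    n = len(y)
    loss = float(-np.mean(np.log(p[np.arange(n), y] + _EPS)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


# ---------------------------------------------------------------------------
# estimator


class SidaIntegrator(TransformerMixin, BaseEstimator):
    """Supervised multi-batch integrator (Siamese network + CCSA loss).

    ``fit(X, y, batches=...)`` trains on stacked per-batch PC coordinates
    ``X`` with cell-type labels ``y`` and per-cell batch identifiers;
    ``transform(X)`` maps cells into the integrated embedding space (the
    second feature layer of the classifier ``h``); ``predict(X)`` returns
    cell-type calls from the softmax head.

    Parameters mirror :class:`SidaConfig`.  Training is deterministic given
    ``seed``.
    """

    def __init__(
        self,
        margin: float = 1.0,
        alpha_sa: float = 1.0,
        alpha_s: float = 1.0,
        alpha_c: float = 1.0,
        n_steps: int = 3000,
        lr: float = 3e-3,
        batch_size: int = 64,
        embedding_dim: int = 64,
        g_out: int = 64,
        g_channels: tuple[int, int] = (16, 32),
        kernel: int = 3,
        h_hidden: int = 128,
        arch: str = "conv",
        sa_squared: bool = True,
        pos_fraction: float = 0.5,
        cells_per_type: int = 400,
        lr_decay: float = 0.1,
        patience: int | None = None,
        seed: int = 0,
    ):
        self.margin = margin
        self.alpha_sa = alpha_sa
        self.alpha_s = alpha_s
        self.alpha_c = alpha_c
        self.n_steps = n_steps
        self.lr = lr
        self.batch_size = batch_size
        self.embedding_dim = embedding_dim
        self.g_out = g_out
        self.g_channels = g_channels
        self.kernel = kernel
        self.h_hidden = h_hidden
        self.arch = arch
        self.sa_squared = sa_squared
        self.pos_fraction = pos_fraction
        self.cells_per_type = cells_per_type
        self.lr_decay = lr_decay
        self.patience = patience
        self.seed = seed

    # -- construction -------------------------------------------------------

    def _config(self) -> SidaConfig:
        return SidaConfig(**{k: getattr(self, k) for k in SidaConfig.__dataclass_fields__})

    def _build(self, n_pcs: int, n_classes: int, rng: np.random.Generator) -> None:
        cfg = self._config()
        if cfg.arch == "conv":
            c1, c2 = cfg.g_channels
            L = n_pcs - 2 * (cfg.kernel - 1)
            if L < 1:
                raise ValueError("input too short for the convolutional branch")
            self.g_ = Sequential(
                [
                    Conv1d(1, c1, cfg.kernel, rng),
                    ReLU(),
                    Conv1d(c1, c2, cfg.kernel, rng),
                    ReLU(),
                    Flatten(),
                    Dense(c2 * L, cfg.g_out, rng),
                ]
            )
        elif cfg.arch == "mlp":
            self.g_ = Sequential(
                [
                    Dense(n_pcs, 2 * cfg.g_out, rng),
                    ReLU(),
                    Dense(2 * cfg.g_out, cfg.g_out, rng),
                ]
            )
        else:
            raise ValueError(f"unknown arch {cfg.arch!r}")
        # h = [feature layer 1, feature layer 2, softmax head]; embedding is
        # the second feature layer's (post-ReLU) output, index 4 below.
        self.h_ = Sequential(
            [
                Dense(cfg.g_out, cfg.h_hidden, rng),
                ReLU(),
                Dense(cfg.h_hidden, cfg.embedding_dim, rng),
                ReLU(),
                Dense(cfg.embedding_dim, n_classes, rng),
            ]
        )

    def _g_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, None, :] if self.arch == "conv" else X

    # -- Siamese branches (identical by construction: one parameter set) ----

    def branch_source(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.g_.forward(self._g_input(X))
        return out

    branch_target = branch_source

    # -- training -----------------------------------------------------------

    def _step(self, pb: PairBatch, opt: Adam) -> tuple[float, float, float, float]:
        cfg_m, sa_sq = self.margin, self.sa_squared
        zs, cs = self.g_.forward(self._g_input(pb.x_source))
        zt, ct = self.g_.forward(self._g_input(pb.x_target))
        l_sa, dzs_sa, dzt_sa = _sa_grads(zs, zt, pb.same_type, sa_sq)
        l_s, dzs_s, dzt_s = _sep_grads(zs, zt, pb.same_type, cfg_m)
        logits, ch = self.h_.forward(zs)
        l_c, dlogits = _ce_grads(logits, pb.y_source)
        total = self.alpha_sa * l_sa + self.alpha_s * l_s + self.alpha_c * l_c
        if not np.isfinite(total):
            raise RuntimeError(
                f"training diverged (non-finite loss at step with source "
                f"{pb.source_batch!r}): L_SA={l_sa}, L_S={l_s}, L_C={l_c}"
            )
        self.g_.zero_grad()
        self.h_.zero_grad()
        dzs_c = self.h_.backward(self.alpha_c * dlogits, ch)
        self.g_.backward(self.alpha_sa * dzs_sa + self.alpha_s * dzs_s + dzs_c, cs)
        self.g_.backward(self.alpha_sa * dzt_sa + self.alpha_s * dzt_s, ct)
        opt.step()
        return l_sa, l_s, l_c, total

    def fit(self, X, y, batches=None, schedule: PairSchedule | None = None):
        """Train on stacked PC coordinates.

        Parameters
        ----------
        X : (n_cells, n_pcs) array
            Per-batch PC coordinates, stacked over batches.
        y : (n_cells,) array of str
            Consolidated cell-type labels.
        batches : (n_cells,) array of str
            Batch identifier per cell (required).
        schedule : optional pre-built rotation schedule.
        """
        from .pairs import draw_pair_batch, make_schedule, subsample_cells

        if batches is None:
            raise ValueError("batches= (per-cell batch ids) is required")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        batches = np.asarray(batches, dtype=object)
        if X.ndim != 2 or len(X) != len(y) or len(y) != len(batches):
            raise ValueError("X, y, batches must align")
        view = PCView.from_arrays(X, y, batches)
        if view.n_batches < 2:
            raise ValueError("need >= 2 batches to integrate")

        self.classes_ = np.array(sorted(set(y.tolist())), dtype=object)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.seed)
        rng_init, rng_sub, rng_pairs = rng.spawn(3)
        self._build(X.shape[1], len(self.classes_), rng_init)

        train_view = subsample_cells(
            view, self.cells_per_type, seed=int(rng_sub.integers(2**31))
        )
        if schedule is None:
            schedule = make_schedule(view.batch_ids, seed=self.seed)
        opt = Adam(self.g_.params() + self.h_.params(), lr=self.lr)

        trace = []
        cycle_len = len(schedule)
        best, stale = np.inf, 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # repeated no-shared-type warnings
            for step_i in range(self.n_steps):
                frac = step_i / max(self.n_steps - 1, 1)
                opt.lr = self.lr * (1.0 - (1.0 - self.lr_decay) * frac)
                src, tgt = schedule.step(step_i)
                pb = draw_pair_batch(
                    train_view,
                    (src, tgt),
                    self.batch_size,
                    pos_fraction=self.pos_fraction,
                    rng=rng_pairs,
                )
                l_sa, l_s, l_c, tot = self._step(pb, opt)
                trace.append((step_i, src, tgt, l_sa, l_s, l_c, tot))
                if self.patience is not None and (step_i + 1) % cycle_len == 0:
                    recent = np.mean([t[-1] for t in trace[-cycle_len:]])
                    if recent < best - 1e-4:
                        best, stale = recent, 0
                    else:
                        stale += 1
                        if stale >= self.patience:
                            break
        self.loss_trace_ = pd.DataFrame(
            trace, columns=["step", "source", "target", "l_sa", "l_s", "l_c", "total"]
        )
        return self

    # -- inference ----------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Integrated embedding: second feature layer of ``h`` after ``g``."""
        check_is_fitted(self, "g_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model trained with {self.n_features_in_}"
            )
        z = self.g_.forward_upto(self._g_input(X), len(self.g_.layers))
        return self.h_.forward_upto(z, 4)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "g_")
        X = np.asarray(X, dtype=float)
        z = self.g_.forward_upto(self._g_input(X), len(self.g_.layers))
        out, _ = self.h_.forward(z)
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


# ---------------------------------------------------------------------------
# module-level wrappers over the estimator


def total_loss(
    pair_batch: PairBatch, model: SidaIntegrator, config: SidaConfig
) -> tuple[float, dict[str, float]]:
    """Evaluate the weighted CCSA objective and its components (no update)."""
    zs = model.branch_source(pair_batch.x_source)
    zt = model.branch_target(pair_batch.x_target)
    l_sa = semantic_alignment_loss(zs, zt, pair_batch.same_type, config.sa_squared)
    l_s = separation_loss(zs, zt, pair_batch.same_type, config.margin)
    logits, _ = model.h_.forward(zs)
    l_c = classification_loss(logits, pair_batch.y_source)
    tot = config.alpha_sa * l_sa + config.alpha_s * l_s + config.alpha_c * l_c
    return tot, {"l_sa": l_sa, "l_s": l_s, "l_c": l_c}


def train(
    pc_view: PCView, schedule: PairSchedule | None = None, config: SidaConfig | None = None
) -> SidaIntegrator:
    """Train an integrator on a per-batch PC view."""
    config = config or SidaConfig()
    X, _, types, batches = pc_view.stacked()
    est = SidaIntegrator(**asdict(config))
    return est.fit(X, types, batches=batches, schedule=schedule)


def embed(model: SidaIntegrator, pc_view: PCView) -> Embedding:
    """Map every cell of every batch into the integrated embedding space."""
    X, ids, types, batches = pc_view.stacked()
    return Embedding(model.transform(X), ids, types, batches)


def save_model(model: SidaIntegrator, path) -> None:
    """Checkpoint: parameters + hyperparameter snapshot (npz)."""
    check_is_fitted(model, "g_")
    params = {f"p{i}": p for i, (p, _) in enumerate(model.g_.params() + model.h_.params())}
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in model.get_params().items()}
    np.savez(
        path,
        __config__=json.dumps(cfg),
        __classes__=np.asarray(model.classes_, dtype=str),
        __n_features__=model.n_features_in_,
        **params,
    )


def load_model(path) -> SidaIntegrator:
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["__config__"]))
    cfg["g_channels"] = tuple(cfg["g_channels"])
    est = SidaIntegrator(**cfg)
    est.classes_ = np.asarray(data["__classes__"], dtype=object)
    est.n_features_in_ = int(data["__n_features__"])
    est._build(est.n_features_in_, len(est.classes_), np.random.default_rng(0))
    for i, (p, _) in enumerate(est.g_.params() + est.h_.params()):
        p[:] = data[f"p{i}"]
    est.loss_trace_ = pd.DataFrame()
    return est
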