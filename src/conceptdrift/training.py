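"""Chronological predict-then-update training and evaluation.

Each epoch replays the graphlets in order.  Co-occurrences at step t are
scored *before* the step's events touch the memory, against 1:1 uniformly
sampled negatives, with binary cross-entropy on the sigmoid scores.  Memory
updates are committed with a one-step lag: the previous step's updates are
re-derived inside the current computation graph (stored states read as
constants), so the recurrent cell and time encoder receive gradients without
backpropagating through the whole history.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import rankdata

from ._tensor import Tensor, scatter_rows
from .events import (
    PairSample,
    SplitSpec,
    TemporalGraph,
    remove_seen_pairs,
    sample_negatives,
)
from .memory import SemanticStateStore, apply_graphlet, graphlet_update
from .nn import MLP, Adam, GRUCell, Linear, Module, MultiHeadAttention, TimeEncoder
from .predictor import NeighborIndex, batched_predictive_embeddings, update_neighbor_index

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "EvalResult",
    "ConceptDriftModel",
    "train",
    "evaluate",
    "auc",
    "average_precision",
    "set_global_seed",
    "dot_product_baseline",
    "snapshot_states",
]


@dataclass
class TrainConfig:
    epochs: int = 8
    lr: float = 3e-3
    batch_size: int | None = None  # pairs per optimization step; None = per-step batch
    seed: int = 0
    negative_ratio: float = 1.0
    data_fraction: float = 1.0
    state_dim: int = 32
    time_dim: int = 8
    heads: int = 2
    attn_dim: int = 32
    neighbor_cap: int | None = 20
    dz: int = 32
    score_hidden: int = 32
    project_embeddings: str = "auto"
    epoch_memory_reset: bool = True
    resample_negatives: bool = True
    exclude_history_negatives: bool = False
    no_attention: bool = False
    freeze_states: bool = False

    def __post_init__(self):
        if not (0 < self.data_fraction <= 1):
            raise ValueError("data_fraction must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class EvalResult:
    auc: float
    ap: float
    n_pos: int
    n_neg: int


def set_global_seed(seed: int | None = None) -> int:
    """Seed python and numpy global RNGs; entropy-based when None."""
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        logger.info("no seed given; using entropy-based seed %d", seed)
    random.seed(seed)
    np.random.seed(seed % (2**32))
    return seed


# ---------------------------------------------------------------------------
# ranking metrics


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative),
    ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc requires both classes")
    ranks = rankdata(scores)  # average ranks for ties
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(scores, labels) -> float:
    """Mean precision at each positive's rank, scores descending; ties are
    broken by stable original index order."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0:
        raise ValueError("average precision requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    cum_pos = np.cumsum(ranked == 1)
    ranksteps = np.arange(1, len(ranked) + 1)
    precisions = cum_pos[ranked == 1] / ranksteps[ranked == 1]
    return float(precisions.mean())


def dot_product_baseline(embeddings: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Frozen-embedding dot-product scores for (i, j) pair rows."""
    E = np.asarray(embeddings, dtype=np.float64)
    pairs = np.asarray(pairs)
    return np.einsum("ij,ij->i", E[pairs[:, 0]], E[pairs[:, 1]])


# ---------------------------------------------------------------------------
# model


class ConceptDriftModel(Module):
    """Bundle of learnable components plus the frozen init embeddings."""

    def __init__(self, embeddings: np.ndarray, concepts: list[str],
                 cfg: TrainConfig):
        self.cfg = cfg
        self.concepts = list(concepts)
        self.vocab_hash = vocab_hash(concepts)
        self.init_matrix = np.asarray(embeddings, dtype=np.float64)
        if self.init_matrix.shape[0] != len(concepts):
            raise ValueError("embedding rows must match vocabulary size")
        d_emb = self.init_matrix.shape[1]
        d = cfg.state_dim
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
        self.projection: Linear | None = None
        use_proj = cfg.project_embeddings == "on" or (
            cfg.project_embeddings == "auto" and d_emb != d
        )
        if not use_proj and d_emb != d:
            raise ValueError("d_emb != state_dim with projection off")
        if use_proj:
            self.projection = Linear(d_emb, d, rng)
        self.time_enc = TimeEncoder(cfg.time_dim, rng)
        self.cell = GRUCell(2 * d + cfg.time_dim, d, rng)
        self.attn = MultiHeadAttention(d + cfg.time_dim, cfg.attn_dim,
                                       cfg.heads, rng)
        self.fuse = MLP([d + cfg.attn_dim, cfg.dz, cfg.dz], rng)
        self.score_head = MLP([cfg.dz, cfg.score_hidden, 1], rng)
        self.no_attention = cfg.no_attention
        self.freeze_states = cfg.freeze_states

    # -- plumbing -------------------------------------------------------------

    def make_store(self) -> SemanticStateStore:
        store = SemanticStateStore(self.init_matrix, self.init_matrix,
                                   self.projection)
        store.reset()
        return store

    def make_index(self) -> NeighborIndex:
        return NeighborIndex(len(self.concepts), self.cfg.neighbor_cap)

    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        params = self.state_dict()
        params["__init_matrix__"] = self.init_matrix
        np.savez(out_dir / "params.npz", **params)
        snap = {f.name: getattr(self.cfg, f.name) for f in fields(TrainConfig)}
        snap["vocab_hash"] = self.vocab_hash
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(snap, fh)
        with open(out_dir / "vocab.txt", "w") as fh:
            fh.write("\n".join(self.concepts) + "\n")
        return out_dir

    @classmethod
    def load(cls, model_dir) -> "ConceptDriftModel":
        model_dir = Path(model_dir)
        with open(model_dir / "config.yaml") as fh:
            snap = yaml.safe_load(fh)
        stored_hash = snap.pop("vocab_hash")
        cfg = TrainConfig(**snap)
        concepts = (model_dir / "vocab.txt").read_text().splitlines()
        with np.load(model_dir / "params.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        init_matrix = params.pop("__init_matrix__")
        model = cls(init_matrix, concepts, cfg)
        if model.vocab_hash != stored_hash:
            raise ValueError("vocabulary hash mismatch")
        model.load_state_dict(params)
        return model

    # -- scoring --------------------------------------------------------------

    def score_logits(self, states_mat: Tensor, index: NeighborIndex,
                     pairs: np.ndarray, t_embed: float) -> Tensor:
        """Traced logits for (B, 2) candidate pair rows."""
        pairs = np.asarray(pairs, dtype=np.int64)
        concepts = np.unique(pairs)
        z = batched_predictive_embeddings(self, states_mat, index, concepts,
                                          t_embed)
        pos_i = np.searchsorted(concepts, pairs[:, 0])
        pos_j = np.searchsorted(concepts, pairs[:, 1])
        zsum = z.take_rows(pos_i) + z.take_rows(pos_j)
        return self.score_head(zsum).reshape(-1)


def vocab_hash(concepts: list[str]) -> str:
    return hashlib.sha256("\n".join(concepts).encode()).hexdigest()


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    y = np.asarray(labels, dtype=np.float64)
    return (logits.softplus() - logits * y).mean()


# ---------------------------------------------------------------------------
# training


def _subsample_events(graph: TemporalGraph, train_end: int, fraction: float,
                      rng: np.random.Generator) -> TemporalGraph:
    train_events = [e for e in graph.events if e.t <= train_end]
    later = [e for e in graph.events if e.t > train_end]
    keep = int(round(fraction * len(train_events)))
    chosen = rng.choice(len(train_events), size=keep, replace=False)
    kept = [train_events[k] for k in sorted(chosen)]
    return TemporalGraph(graph.concepts, graph.horizon, kept + later,
                         graph.names)


def train(
    graph: TemporalGraph,
    split: SplitSpec,
    embeddings: np.ndarray,
    cfg: TrainConfig,
) -> tuple[ConceptDriftModel, list[dict]]:
    """Train on steps 1..train_end, select the checkpoint with best
    validation AUC at val_step, and return it with per-epoch history."""
    split.validate(graph)
    if not any(e.t <= split.train_end for e in graph.events):
        raise ValueError("no training events before train_end")

    seq = np.random.SeedSequence([cfg.seed, 1])
    rng_sub, rng_neg_root = [np.random.default_rng(s) for s in seq.spawn(2)]
    eval_seed = cfg.seed + 104729

    train_graph = graph
    if cfg.data_fraction < 1.0:
        train_graph = _subsample_events(graph, split.train_end,
                                        cfg.data_fraction, rng_sub)

    model = ConceptDriftModel(embeddings, graph.concepts, cfg)
    opt = Adam(model.parameters(), lr=cfg.lr)

    fixed_negatives: dict[int, list[PairSample]] = {}
    history: list[dict] = []
    best = (-1.0, None)

    store = model.make_store()
    index = model.make_index()
    for epoch in range(cfg.epochs):
        if epoch > 0:
            if cfg.epoch_memory_reset:
                store = model.make_store()
            else:
                store.last_update[:] = 0
                store.current_step = 0
            index = model.make_index()
        pending: tuple[list, int] | None = None
        loss_sum = 0.0
        n_scored = 0

        for t in range(1, split.train_end + 1):
            events_t = train_graph.events_at(t)
            positives = [PairSample(e.i, e.j, t, 1) for e in events_t]
            if positives:
                if cfg.resample_negatives or t not in fixed_negatives:
                    negs = sample_negatives(
                        positives, train_graph, cfg.negative_ratio,
                        exclude_history=cfg.exclude_history_negatives,
                        rng=rng_neg_root,
                    )
                    if not cfg.resample_negatives:
                        fixed_negatives[t] = negs
                else:
                    negs = fixed_negatives[t]
                samples = positives + negs
                pairs = np.array([[s.i, s.j] for s in samples])
                labels = np.array([s.label for s in samples])

                n = len(samples)
                bs = cfg.batch_size or n
                for lo in range(0, n, bs):
                    sl = slice(lo, min(lo + bs, n))
                    states_mat = _traced_states(model, store, pending)
                    logits = model.score_logits(states_mat, index,
                                                pairs[sl], float(t - 1))
                    loss = bce_with_logits(logits, labels[sl])
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    loss_sum += float(loss.data) * (sl.stop - sl.start)
                    n_scored += sl.stop - sl.start

            if pending is not None and not model.freeze_states:
                apply_graphlet(store, model.cell, model.time_enc,
                               pending[0], pending[1])
            elif pending is not None:
                store.current_step = pending[1]
            pending = (events_t, t)
            update_neighbor_index(index, events_t)

        if pending is not None and not model.freeze_states:
            apply_graphlet(store, model.cell, model.time_enc,
                           pending[0], pending[1])

        mean_loss = loss_sum / max(n_scored, 1)
        val = evaluate(model, graph, split.val_step, seed=eval_seed)
        history.append({
            "epoch": epoch,
            "train_loss": mean_loss,
            "val_auc": val.auc,
            "val_ap": val.ap,
        })
        logger.info("epoch %d loss %.4f val_auc %.4f val_ap %.4f",
                    epoch, mean_loss, val.auc, val.ap)
        if val.auc > best[0]:
            best = (val.auc, model.state_dict())

    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def _traced_states(model: ConceptDriftModel, store: SemanticStateStore,
                   pending: tuple[list, int] | None) -> Tensor:
    """Stored states as constants, with the lagged step's updates re-derived
    in-graph (and the projection traced while memory is still at init)."""
    if pending is None or model.freeze_states or not pending[0]:
        if model.projection is not None and store.current_step == 0:
            return model.projection(Tensor(store.init_matrix))
        return Tensor(store.states)
    idx, rows = graphlet_update(store, model.cell, model.time_enc,
                                pending[0], pending[1], traced=True)
    return scatter_rows(store.states, idx, rows)


# ---------------------------------------------------------------------------
# evaluation


def replay(model: ConceptDriftModel, graph: TemporalGraph, upto: int
           ) -> tuple[SemanticStateStore, NeighborIndex]:
    """Numerically replay graphlets 1..upto through the trained modules."""
    store = model.make_store()
    index = model.make_index()
    for t in range(1, upto + 1):
        events_t = graph.events_at(t)
        if not model.freeze_states:
            apply_graphlet(store, model.cell, model.time_enc, events_t, t)
        else:
            store.current_step = t
        update_neighbor_index(index, events_t)
    return store, index


def snapshot_states(model: ConceptDriftModel, graph: TemporalGraph,
                    upto: int | None = None) -> dict[int, np.ndarray]:
    """Per-step copies of the state matrix during a replay (step 0 = init)."""
    upto = graph.horizon if upto is None else upto
    store = model.make_store()
    snaps = {0: store.states.copy()}
    for t in range(1, upto + 1):
        if not model.freeze_states:
            apply_graphlet(store, model.cell, model.time_enc,
                           graph.events_at(t), t)
        else:
            store.current_step = t
        snaps[t] = store.states.copy()
    return snaps


def evaluate(model: ConceptDriftModel, graph: TemporalGraph, step: int,
             seed: int = 0) -> EvalResult:
    """Score step's co-occurrences (leakage-removed) against 1:1 negatives
    using predictive embeddings built from history through step - 1."""
    if step < 1 or step > graph.horizon:
        raise ValueError("evaluation step outside graph horizon")
    pos_pairs = sorted(
        remove_seen_pairs({e.pair for e in graph.events_at(step)}, graph, step)
    )
    if not pos_pairs:
        raise ValueError(f"no surviving positives at step {step}")
    positives = [PairSample(i, j, step, 1) for i, j in pos_pairs]
    negatives = sample_negatives(positives, graph, 1.0, seed=seed)
    samples = positives + negatives
    pairs = np.array([[s.i, s.j] for s in samples])
    labels = np.array([s.label for s in samples])

    store, index = replay(model, graph, step - 1)
    logits = model.score_logits(Tensor(store.states), index, pairs,
                                float(step - 1))
    scores = logits.sigmoid().data
    return EvalResult(
        auc=auc(scores, labels),
        ap=average_precision(scores, labels),
        n_pos=len(positives),
        n_neg=len(negatives),
    )
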