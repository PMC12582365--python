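"""Predictive embeddings and pair scoring.

A concept's query is its current state concatenated with an encoding of the
current step; keys/values are its neighbors' current states concatenated
with encodings of their *first* co-occurrence steps.  Multi-head cross
attention summarizes the neighborhood, an MLP fuses it with the state into a
predictive embedding, and a symmetric MLP head scores candidate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat
from .events import EdgeEvent
from .memory import SemanticStateStore, TimeEncoder, encode_time
from .nn import MLP, MultiHeadAttention

__all__ = [
    "NeighborIndex",
    "AttentionBlock",
    "PredictiveEmbedding",
    "ScoreHead",
    "update_neighbor_index",
    "build_query",
    "build_keys_values",
    "cross_attention",
    "predictive_embedding",
    "score_pair",
]

AttentionBlock = MultiHeadAttention
ScoreHead = MLP


@dataclass
class PredictiveEmbedding:
    vector: np.ndarray
    concept: int
    t: int


class NeighborIndex:
    """Per-concept map neighbor -> first co-occurrence step, with a cap."""

    def __init__(self, n_concepts: int, cap: int | None = 20):
        if cap is not None and cap < 1:
            raise ValueError("cap must be positive or None")
        self.first_seen: list[dict[int, int]] = [{} for _ in range(n_concepts)]
        self.cap = cap

    def neighbors(self, i: int) -> dict[int, int]:
        return self.first_seen[i]

    def capped(self, i: int) -> list[tuple[int, int]]:
        """(neighbor, first step) pairs kept under the cap.

        When the neighborhood exceeds the cap, the neighbors with the
        largest first-co-occurrence steps are kept; ties break on the
        smaller neighbor index for determinism.
        """
        items = sorted(
            self.first_seen[i].items(), key=lambda kv: (-kv[1], kv[0])
        )
        if self.cap is not None:
            items = items[: self.cap]
        return sorted(items)

    def copy(self) -> "NeighborIndex":
        out = NeighborIndex(len(self.first_seen), self.cap)
        out.first_seen = [dict(d) for d in self.first_seen]
        return out


def update_neighbor_index(
    index: NeighborIndex, events: list[EdgeEvent]
) -> NeighborIndex:
    """Record first interactions from one graphlet (symmetric)."""
    for e in events:
        index.first_seen[e.i].setdefault(e.j, e.t)
        index.first_seen[e.j].setdefault(e.i, e.t)
    return index


def build_query(
    store: SemanticStateStore, enc: TimeEncoder, i: int, t: int
) -> np.ndarray:
    """s_i(t) || phi(t)."""
    return np.concatenate([store.states[i], encode_time(enc, t)])


def build_keys_values(
    store: SemanticStateStore,
    enc: TimeEncoder,
    index: NeighborIndex,
    i: int,
    t: int,
) -> list[np.ndarray]:
    """One s_n(t) || phi(t_n) vector per (capped) neighbor n of i."""
    out = []
    for n, t_n in index.capped(i):
        out.append(np.concatenate([store.states[n], encode_time(enc, t_n)]))
    return out


def cross_attention(
    block: AttentionBlock, q: np.ndarray, kv: list[np.ndarray]
) -> np.ndarray:
    """Single-query multi-head attention; empty kv gives the zero vector."""
    q = np.asarray(q, dtype=np.float64)
    if not kv:
        return np.zeros(block.d_attn)
    K = np.stack(kv)[None, :, :]
    mask = np.ones((1, K.shape[1]), dtype=bool)
    return block(Tensor(q[None, :]), Tensor(K), mask).data[0]


def predictive_embedding(
    mlp_fuse: MLP,
    store: SemanticStateStore,
    i: int,
    t: int,
    h: np.ndarray,
) -> PredictiveEmbedding:
    """z_i(t) = MLP(s_i(t) || h)."""
    x = np.concatenate([store.states[i], np.asarray(h, dtype=np.float64)])
    return PredictiveEmbedding(mlp_fuse(Tensor(x[None, :])).data[0], i, t)


def score_pair(
    head: ScoreHead, z_i: PredictiveEmbedding, z_j: PredictiveEmbedding
) -> float:
    """sigma(MLP(z_i + z_j)); symmetric in its arguments."""
    if z_i.t != z_j.t:
        raise ValueError("predictive embeddings from different steps")
    logit = head(Tensor((z_i.vector + z_j.vector)[None, :]))
    return float(logit.sigmoid().data[0, 0])


def batched_predictive_embeddings(
    model,
    states_mat: Tensor,
    index: NeighborIndex,
    concepts: np.ndarray,
    t_embed: float,
) -> Tensor:
    """Traced predictive embeddings z for a batch of concepts.

    `model` bundles the time encoder, attention block and fusion MLP (see
    training.ConceptDriftModel).  `states_mat` may mix constant rows with
    traced ones.
    """
    U = len(concepts)
    d = states_mat.shape[1]
    s = states_mat.take_rows(concepts)
    phi_t = model.time_enc(np.full(U, float(t_embed)))
    if model.no_attention:
        h = Tensor(np.zeros((U, model.attn.d_attn)))
    else:
        caps = [index.capped(int(c)) for c in concepts]
        N = max((len(c) for c in caps), default=0)
        if N == 0:
            h = Tensor(np.zeros((U, model.attn.d_attn)))
        else:
            nb_idx = np.zeros((U, N), dtype=np.int64)
            nb_t = np.zeros((U, N), dtype=np.float64)
            mask = np.zeros((U, N), dtype=bool)
            for r, cap in enumerate(caps):
                for k, (n, t_n) in enumerate(cap):
                    nb_idx[r, k] = n
                    nb_t[r, k] = t_n
                    mask[r, k] = True
            nb_states = states_mat.take_rows(nb_idx.ravel()).reshape(U, N, d)
            phi_nb = model.time_enc(nb_t.ravel()).reshape(U, N, model.time_enc.d_time)
            kv = concat([nb_states, phi_nb], axis=-1)
            q = concat([s, phi_t], axis=-1)
            h = model.attn(q, kv, mask)
    return model.fuse(concat([s, h], axis=-1))
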