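"""Evolving per-concept semantic states.

States start from a (possibly linearly projected) embedding matrix and are
updated whenever a concept co-occurs: the update message concatenates both
endpoint states with a functional encoding of the time since the concept's
last update, and a gated recurrent cell integrates it with the prior state.
All reads within one graphlet use pre-update states, and multiple messages
to one concept are mean-aggregated, so updates are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat
from .events import EdgeEvent
from .nn import GRUCell, Linear, TimeEncoder

__all__ = [
    "SemanticStateStore",
    "ContextMessage",
    "IntegrationCell",
    "TimeEncoder",
    "init_states",
    "encode_time",
    "context_aggregate",
    "aggregate_messages",
    "contextual_integrate",
    "apply_graphlet",
    "graphlet_update",
]

IntegrationCell = GRUCell


@dataclass
class ContextMessage:
    """Aggregated update context for one concept at one step."""

    vector: np.ndarray
    target: int
    t: int


class SemanticStateStore:
    """Matrix of per-concept states plus last-update bookkeeping."""

    def __init__(self, states: np.ndarray, init_matrix: np.ndarray,
                 projection: Linear | None = None):
        self.states = np.asarray(states, dtype=np.float64)
        self.init_matrix = np.asarray(init_matrix, dtype=np.float64)
        self.projection = projection
        self.last_update = np.zeros(self.states.shape[0], dtype=np.int64)
        self.current_step = 0

    @property
    def n_concepts(self) -> int:
        return self.states.shape[0]

    @property
    def d(self) -> int:
        return self.states.shape[1]

    def reset(self) -> None:
        """Re-project the init matrix and rewind the clock."""
        if self.projection is not None:
            self.states = self.projection(Tensor(self.init_matrix)).data.copy()
        else:
            self.states = self.init_matrix.copy()
        self.last_update[:] = 0
        self.current_step = 0

    def copy(self) -> "SemanticStateStore":
        out = SemanticStateStore(self.states.copy(), self.init_matrix,
                                 self.projection)
        out.last_update = self.last_update.copy()
        out.current_step = self.current_step
        return out


def init_states(
    embeddings: np.ndarray,
    d: int,
    projection: str = "auto",
    rng: np.random.Generator | None = None,
) -> SemanticStateStore:
    """Initialize states from an embedding matrix.

    projection: "off" requires d_emb == d (identity); "on" always inserts a
    learnable linear map; "auto" inserts one only when dimensions differ.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("embeddings must be a 2-D matrix")
    d_emb = X.shape[1]
    if projection not in ("auto", "on", "off"):
        raise ValueError("projection must be auto|on|off")
    use_proj = projection == "on" or (projection == "auto" and d_emb != d)
    if not use_proj and d_emb != d:
        raise ValueError(f"d_emb={d_emb} != d={d} with projection disabled")
    proj = None
    if use_proj:
        proj = Linear(d_emb, d, rng or np.random.default_rng(0))
        states = proj(Tensor(X)).data.copy()
    else:
        states = X.copy()
    return SemanticStateStore(states, X, proj)


def encode_time(enc: TimeEncoder, delta_or_t: float) -> np.ndarray:
    """Length-d_time encoding: linear first component, cosines after."""
    return enc(float(delta_or_t)).data[0]


def context_aggregate(
    store: SemanticStateStore, enc: TimeEncoder, i: int, j: int, t: int
) -> ContextMessage:
    """s_i(tp_i) || s_j(tp_j) || phi(t - tp_i); no state mutation."""
    tp_i = int(store.last_update[i])
    if t < tp_i:
        raise ValueError(f"t={t} precedes last update {tp_i} of concept {i}")
    vec = np.concatenate(
        [store.states[i], store.states[j], encode_time(enc, t - tp_i)]
    )
    return ContextMessage(vec, i, t)


def aggregate_messages(messages: list[ContextMessage]) -> ContextMessage:
    """Elementwise mean of same-target, same-step messages."""
    if not messages:
        raise ValueError("no messages to aggregate")
    tgt, t = messages[0].target, messages[0].t
    if any(m.target != tgt or m.t != t for m in messages):
        raise ValueError("messages must share target and step")
    if len(messages) == 1:
        return messages[0]
    vec = np.mean([m.vector for m in messages], axis=0)
    return ContextMessage(vec, tgt, t)


def contextual_integrate(
    cell: IntegrationCell, msg: ContextMessage, s_prev: np.ndarray
) -> np.ndarray:
    """One gated-recurrent step integrating a context message."""
    out = cell(Tensor(msg.vector[None, :]), Tensor(np.asarray(s_prev)[None, :]))
    return out.data[0]


def _step_messages(
    store: SemanticStateStore,
    enc: TimeEncoder,
    events: list[EdgeEvent],
    t: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-aggregated update messages per touched concept.

    Returns (sorted concept indices, message matrix).  Messages are built
    from pre-step states; both endpoints of each event receive a message.
    Events are canonicalized before averaging so the result is independent
    of list order, bitwise.
    """
    per_target: dict[int, list[tuple[int, int]]] = {}
    for e in events:
        if e.t != t:
            raise ValueError("events must all be at the given step")
        per_target.setdefault(e.i, []).append((e.i, e.j))
        per_target.setdefault(e.j, []).append((e.j, e.i))
    idx = np.array(sorted(per_target), dtype=np.int64)
    d, dt = store.d, enc.d_time
    msgs = np.empty((len(idx), 2 * d + dt), dtype=np.float64)
    for row, tgt in enumerate(idx):
        pairs = sorted(set(per_target[tgt]))
        vecs = np.empty((len(pairs), 2 * d + dt))
        delta = float(t - store.last_update[tgt])
        phi = encode_time(enc, delta)
        for k, (_, other) in enumerate(pairs):
            vecs[k, :d] = store.states[tgt]
            vecs[k, d : 2 * d] = store.states[other]
            vecs[k, 2 * d :] = phi
        msgs[row] = vecs.mean(axis=0)
    return idx, msgs


def graphlet_update(
    store: SemanticStateStore,
    cell: IntegrationCell,
    enc: TimeEncoder,
    events: list[EdgeEvent],
    t: int,
    traced: bool = False,
) -> tuple[np.ndarray, Tensor]:
    """Compute (but do not commit) the state rows changed by a graphlet.

    With traced=True the returned rows carry gradient structure for the
    recurrent cell and time encoder; message contents read the stored states
    as constants.
    """
    idx, msgs = _step_messages(store, enc, events, t)
    if len(idx) == 0:
        return idx, Tensor(np.zeros((0, store.d)))
    d = store.d
    h_prev = Tensor(store.states[idx])
    if traced:
        # rebuild the time-encoding slice in-graph so enc gets gradients
        deltas = (t - store.last_update[idx]).astype(np.float64)
        phi = enc(deltas)
        x = concat([Tensor(msgs[:, : 2 * d]), phi], axis=-1)
    else:
        x = Tensor(msgs)
    return idx, cell(x, h_prev)


def apply_graphlet(
    store: SemanticStateStore,
    cell: IntegrationCell,
    enc: TimeEncoder,
    events: list[EdgeEvent],
    t: int | None = None,
) -> SemanticStateStore:
    """Commit one graphlet's updates to the store (simultaneous semantics)."""
    if t is None:
        if not events:
            return store
        t = events[0].t
    if t <= store.current_step:
        raise ValueError(
            f"graphlet at t={t} is out of order (already at "
            f"{store.current_step})"
        )
    idx, rows = graphlet_update(store, cell, enc, events, t)
    if len(idx):
        store.states[idx] = rows.data
        store.last_update[idx] = t
    store.current_step = t
    return store
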