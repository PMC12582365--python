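"""Synthetic dynamic co-occurrence graphs with planted drift.

Concepts live in a latent space, seeded around cluster centers.  Positions
take a Gaussian random walk each step; a set of planted pairs is additionally
contracted toward each other so they converge over time.  Edges are sampled
with a logistic probability in latent distance, so nearby concepts share
neighbors by construction.  Planted pairs are withheld from the edge process
until their distance drops below a threshold, which makes them late-emerging
positives.  Embeddings are a noisy linear readout of the *initial* positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EdgeEvent, TemporalGraph

__all__ = ["DriftConfig", "generate_dynamic_graph", "generate_embeddings"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class DriftConfig:
    n_concepts: int = 300
    horizon: int = 12
    latent_dim: int = 8
    n_clusters: int = 5
    drift_rate: float = 0.6
    converge_pairs: int = 30
    converge_rate: float = 0.28
    converge_threshold: float = 4.0
    edge_scale: float = 2.5
    cluster_spread: float = 4.0
    within_spread: float = 1.0
    embedding_noise: float = 5.0
    d_emb: int = 32
    seed: int = 0

    def __post_init__(self):
        if min(self.n_concepts, self.horizon, self.latent_dim,
               self.n_clusters, self.d_emb) < 1:
            raise ValueError("counts must be positive")
        if self.drift_rate < 0:
            raise ValueError("drift_rate must be >= 0")
        if not (0 <= self.converge_rate < 1):
            raise ValueError("converge_rate must be in [0, 1)")
        if self.converge_pairs < 0 or 2 * self.converge_pairs > self.n_concepts:
            raise ValueError("converge_pairs must be <= n_concepts/2")


@dataclass
class SyntheticGraph:
    graph: TemporalGraph
    trajectories: np.ndarray  # (horizon+1, n_concepts, latent_dim)
    planted_pairs: list[tuple[int, int]] = field(default_factory=list)


def generate_dynamic_graph(cfg: DriftConfig) -> SyntheticGraph:
    """Simulate latent trajectories and the induced temporal graph."""
    rng = np.random.default_rng(cfg.seed)
    n, T, D = cfg.n_concepts, cfg.horizon, cfg.latent_dim

    centers = rng.normal(0.0, cfg.cluster_spread, size=(cfg.n_clusters, D))
    assign = rng.integers(0, cfg.n_clusters, size=n)
    x = centers[assign] + rng.normal(0.0, cfg.within_spread, size=(n, D))

    # planted pairs across different clusters where possible
    order = rng.permutation(n)
    planted: list[tuple[int, int]] = []
    used: set[int] = set()
    pool = list(order)
    while len(planted) < cfg.converge_pairs and pool:
        a = pool.pop()
        if a in used:
            continue
        partner = None
        for k, b in enumerate(pool):
            if b not in used and assign[b] != assign[a]:
                partner = pool.pop(k)
                break
        if partner is None:
            for k, b in enumerate(pool):
                if b not in used:
                    partner = pool.pop(k)
                    break
        if partner is None:
            break
        used.update((a, partner))
        planted.append((min(a, partner), max(a, partner)))
    planted.sort()

    # stagger convergence onsets so planted pairs emerge throughout the run
    if planted:
        onsets = rng.integers(1, max(2, T - 2), size=len(planted))
    traj = np.empty((T + 1, n, D))
    traj[0] = x
    events: list[EdgeEvent] = []
    for t in range(1, T + 1):
        x = x + rng.normal(0.0, cfg.drift_rate, size=(n, D))
        for k, (a, b) in enumerate(planted):
            if t < onsets[k]:
                continue
            mid = 0.5 * (x[a] + x[b])
            x[a] = x[a] + cfg.converge_rate * (mid - x[a])
            x[b] = x[b] + cfg.converge_rate * (mid - x[b])
        traj[t] = x

        dists = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
        probs = _sigmoid(cfg.edge_scale - dists)
        iu, ju = np.triu_indices(n, k=1)
        draw = rng.random(len(iu)) < probs[iu, ju]
        withheld = np.zeros(len(iu), dtype=bool)
        if planted:
            pl = np.array(planted)
            far = dists[pl[:, 0], pl[:, 1]] >= cfg.converge_threshold
            if far.any():
                flat = {(a, b) for (a, b), f in zip(planted, far) if f}
                withheld = np.fromiter(
                    ((int(a), int(b)) in flat for a, b in zip(iu, ju)),
                    dtype=bool, count=len(iu),
                )
        draw &= ~withheld
        for a, b in zip(iu[draw], ju[draw]):
            events.append(EdgeEvent(t, int(a), int(b)))

    if not events:
        raise ValueError(
            "configuration produced zero edges; raise edge_scale or lower "
            "cluster_spread"
        )
    concepts = [f"C{k:05d}" for k in range(n)]
    graph = TemporalGraph(concepts, T, events, [f"concept {k}" for k in range(n)])
    return SyntheticGraph(graph, traj, planted)


def generate_embeddings(
    synth: SyntheticGraph,
    cfg: DriftConfig,
    linear_map: np.ndarray | None = None,
) -> np.ndarray:
    """Noisy linear readout of the initial latent positions."""
    rng = np.random.default_rng(cfg.seed + 1)
    x0 = synth.trajectories[0]
    if linear_map is None:
        linear_map = rng.normal(
            0.0, 1.0 / np.sqrt(cfg.latent_dim), size=(cfg.latent_dim, cfg.d_emb)
        )
    if linear_map.shape[0] != cfg.latent_dim:
        raise ValueError("linear map rows must equal latent_dim")
    E = x0 @ linear_map
    if cfg.embedding_noise > 0:
        E = E + rng.normal(0.0, cfg.embedding_noise, size=E.shape)
    return E
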