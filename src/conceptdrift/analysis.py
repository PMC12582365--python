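"""Drift diagnostics: neighborhood-overlap statistics and 2-D trajectory
projections of evolving semantic states."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .events import TemporalGraph

__all__ = [
    "OverlapReport",
    "TrajectoryRecord",
    "jaccard",
    "overlap_report",
    "track_trajectories",
    "convergence_curve",
]


@dataclass(frozen=True)
class OverlapReport:
    t: int
    cooc_mean: float
    cooc_median: float
    noncooc_mean: float
    noncooc_median: float
    n_cooc: int
    n_noncooc: int

    @property
    def gap(self) -> float:
        return self.cooc_mean - self.noncooc_mean


@dataclass
class TrajectoryRecord:
    concept: int
    steps: list[int]
    coords: np.ndarray  # (len(steps), 2)


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|, with 0 for two empty sets."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def overlap_report(
    graph: TemporalGraph, t: int, n_samples: int = 500, seed: int = 0,
    new_pairs_only: bool = False,
) -> OverlapReport:
    """Compare neighborhood overlap (history strictly before t) of pairs
    co-occurring at t against uniformly sampled non-co-occurring pairs.

    Using pre-t neighborhoods keeps the statistic predictive rather than
    circular.  With new_pairs_only, co-occurring pairs already seen at
    earlier steps are excluded, mirroring the leakage rule used at
    evaluation time.
    """
    if t < 1 or t > graph.horizon:
        raise ValueError("step outside horizon")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    cooc_all = {e.pair for e in graph.events_at(t)}
    if new_pairs_only:
        from .events import remove_seen_pairs

        cooc = sorted(remove_seen_pairs(cooc_all, graph, t))
    else:
        cooc = sorted(cooc_all)
    if not cooc:
        raise ValueError(f"no co-occurring pairs at step {t}")
    rng = np.random.default_rng(seed)
    if len(cooc) > n_samples:
        pick = rng.choice(len(cooc), size=n_samples, replace=False)
        cooc = [cooc[k] for k in sorted(pick)]

    nbrs = graph.neighborhoods_until(t - 1)
    cooc_set = {e.pair for e in graph.events_at(t)}
    cooc_j = np.array([jaccard(nbrs[i], nbrs[j]) for i, j in cooc])

    non: list[float] = []
    n = graph.n_concepts
    tries = 0
    while len(non) < n_samples:
        tries += 1
        if tries > 1000 * n_samples:
            raise RuntimeError("could not sample non-co-occurring pairs")
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        if (min(i, j), max(i, j)) in cooc_set:
            continue
        non.append(jaccard(nbrs[i], nbrs[j]))
    non_j = np.array(non)

    return OverlapReport(
        t=t,
        cooc_mean=float(cooc_j.mean()),
        cooc_median=float(np.median(cooc_j)),
        noncooc_mean=float(non_j.mean()),
        noncooc_median=float(np.median(non_j)),
        n_cooc=len(cooc_j),
        n_noncooc=len(non_j),
    )


def track_trajectories(
    state_snapshots: dict[int, np.ndarray], concepts: list[int]
) -> list[TrajectoryRecord]:
    """Project per-step states of selected concepts onto a shared 2-D
    principal-component basis fit on the pooled rows.

    Sign convention: the first nonzero loading of each component is made
    positive, so the projection is deterministic.
    """
    if len(state_snapshots) < 2:
        raise ValueError("need at least two state snapshots")
    steps = sorted(state_snapshots)
    concepts = list(concepts)
    pooled = np.vstack(
        [state_snapshots[t][concepts] for t in steps]
    )
    if np.unique(pooled, axis=0).shape[0] < 2:
        raise ValueError("need at least two distinct state vectors")
    pca = PCA(n_components=2, svd_solver="full")
    proj = pca.fit_transform(pooled)
    for k in range(2):
        load = pca.components_[k]
        nz = np.nonzero(load)[0]
        if len(nz) and load[nz[0]] < 0:
            proj[:, k] *= -1
    proj = proj.reshape(len(steps), len(concepts), 2)
    return [
        TrajectoryRecord(c, steps, proj[:, k, :].copy())
        for k, c in enumerate(concepts)
    ]


def convergence_curve(
    record_i: TrajectoryRecord, record_j: TrajectoryRecord
) -> np.ndarray:
    """Projected Euclidean distance per captured step."""
    if record_i.steps != record_j.steps:
        raise ValueError("trajectory capture steps differ")
    return np.linalg.norm(record_i.coords - record_j.coords, axis=1)
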