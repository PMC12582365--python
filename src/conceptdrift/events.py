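"""Temporal co-occurrence graph construction.

Annotation records (article, year, concept) are filtered, grouped by article
and expanded into unordered co-occurrence edge events, one graphlet per time
step.  Time steps are 1-based; step 0 is the reserved empty graphlet.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationRecord",
    "EdgeEvent",
    "TemporalGraph",
    "SplitSpec",
    "PairSample",
    "parse_annotations",
    "filter_annotations",
    "build_temporal_graph",
    "neighborhood",
    "remove_seen_pairs",
    "sample_negatives",
    "write_edge_events",
    "read_edge_events",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """One concept mention in one article, raw as read."""

    article_id: str
    year: int
    concept_id: str
    concept_type: str
    concept_name: str


@dataclass(frozen=True, order=True)
class EdgeEvent:
    """Unordered co-occurrence (i, j) observed at time step t, stored i < j."""

    t: int
    i: int
    j: int

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError(f"self-edge ({self.i},{self.j}) not allowed")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class TemporalGraph:
    """Vocabulary plus chronologically sorted edge events over steps 0..T."""

    concepts: list[str]
    horizon: int
    events: list[EdgeEvent]
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.names:
            self.names = list(self.concepts)
        n = len(self.concepts)
        for e in self.events:
            if e.t < 1 or e.t > self.horizon:
                raise ValueError(f"event at t={e.t} outside [1, {self.horizon}]")
            if e.j >= n or e.i < 0:
                raise ValueError(f"event index out of range: {e}")
        self.events = sorted(set(self.events), key=lambda e: (e.t, e.i, e.j))
        self._by_step: dict[int, list[EdgeEvent]] = {}
        for e in self.events:
            self._by_step.setdefault(e.t, []).append(e)

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    def events_at(self, t: int) -> list[EdgeEvent]:
        return self._by_step.get(t, [])

    def pairs_before(self, t: int) -> set[tuple[int, int]]:
        """All unordered pairs with at least one event at a step < t."""
        return {e.pair for e in self.events if e.t < t}

    def neighborhoods_until(self, t: int) -> list[set[int]]:
        """Neighbor sets per concept using events at steps in [1, t]."""
        nbrs: list[set[int]] = [set() for _ in range(self.n_concepts)]
        for e in self.events:
            if e.t > t:
                break
            nbrs[e.i].add(e.j)
            nbrs[e.j].add(e.i)
        return nbrs

    def __eq__(self, other) -> bool:
        if not isinstance(other, TemporalGraph):
            return NotImplemented
        return (
            self.concepts == other.concepts
            and self.names == other.names
            and self.horizon == other.horizon
            and self.events == other.events
        )


@dataclass(frozen=True)
class SplitSpec:
    """Chronological split: train through `train_end`, then val/test steps."""

    train_end: int
    val_step: int
    test_step: int

    def __post_init__(self):
        if not (0 < self.train_end < self.val_step < self.test_step):
            raise ValueError("require 0 < train_end < val_step < test_step")

    def validate(self, graph: TemporalGraph) -> None:
        if self.test_step > graph.horizon:
            raise ValueError("test_step exceeds graph horizon")


@dataclass(frozen=True)
class PairSample:
    """Labeled candidate co-occurrence at a target step."""

    i: int
    j: int
    t: int
    label: int

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-pair sample")

    @property
    def pair(self) -> tuple[int, int]:
        return (min(self.i, self.j), max(self.i, self.j))


# ---------------------------------------------------------------------------
# parsing and filtering


def parse_annotations(path) -> list[AnnotationRecord]:
    """Read tab-separated annotation records.

    Columns: article_id, year, concept_id, concept_type, concept_name.
    Lines starting with '#' are comments.  A line matching the header names
    is skipped.  Malformed lines are skipped and reported via logging with
    their 1-based line numbers.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    bad: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                bad.append(lineno)
                continue
            if lineno == 1 and cols[0] == "article_id":
                continue
            try:
                year = int(cols[1])
            except ValueError:
                bad.append(lineno)
                continue
            records.append(
                AnnotationRecord(cols[0], year, cols[2], cols[3], cols[4])
            )
    if bad:
        logger.warning(
            "%s: skipped %d malformed line(s): %s", path, len(bad), bad
        )
    return records


def filter_annotations(
    records: list[AnnotationRecord], mesh_tag: str = "MeSH"
) -> list[AnnotationRecord]:
    """Drop records with blank concept ids or a concept_type other than
    `mesh_tag`; order preserved."""
    return [
        r for r in records
        if r.concept_id.strip() and r.concept_type == mesh_tag
    ]


def build_temporal_graph(
    records: list[AnnotationRecord], first_year: int, last_year: int
) -> TemporalGraph:
    """Expand per-article concept sets into pairwise edge events.

    Time step t = year - first_year + 1, so step 0 stays empty.  Duplicate
    (i, j, t) events collapse to one.
    """
    if last_year < first_year:
        raise ValueError("empty year range")
    for r in records:
        if not (first_year <= r.year <= last_year):
            raise ValueError(
                f"record year {r.year} outside [{first_year}, {last_year}]"
            )
    ids = sorted({r.concept_id for r in records})
    index = {cid: k for k, cid in enumerate(ids)}
    names = [""] * len(ids)
    for r in records:
        names[index[r.concept_id]] = r.concept_name

    by_article: dict[tuple[str, int], set[int]] = {}
    for r in records:
        by_article.setdefault((r.article_id, r.year), set()).add(
            index[r.concept_id]
        )

    horizon = last_year - first_year + 1
    events: set[EdgeEvent] = set()
    for (_, year), concepts in by_article.items():
        t = year - first_year + 1
        for a, b in itertools.combinations(sorted(concepts), 2):
            events.add(EdgeEvent(t, a, b))
    return TemporalGraph(ids, horizon, sorted(events), names)


# ---------------------------------------------------------------------------
# neighborhoods, leakage, negatives


def neighborhood(graph: TemporalGraph, i: int, t: int) -> set[int]:
    """Concepts sharing an event with `i` at any step in [1, t]."""
    if not (0 <= i < graph.n_concepts):
        raise IndexError(f"concept index {i} out of range")
    if not (0 <= t <= graph.horizon):
        raise IndexError(f"time step {t} out of range")
    out: set[int] = set()
    for e in graph.events:
        if e.t > t:
            break
        if e.i == i:
            out.add(e.j)
        elif e.j == i:
            out.add(e.i)
    return out


def remove_seen_pairs(
    candidates: set[tuple[int, int]], graph: TemporalGraph, before: int
) -> set[tuple[int, int]]:
    """Drop candidate pairs that already had an event at any step < before."""
    seen = graph.pairs_before(before)
    return {
        (i, j) for (i, j) in candidates
        if (min(i, j), max(i, j)) not in seen
    }


def sample_negatives(
    positives: list[PairSample],
    graph: TemporalGraph,
    ratio: float = 1.0,
    seed: int = 0,
    exclude_history: bool = False,
    rng: np.random.Generator | None = None,
) -> list[PairSample]:
    """Uniformly sample non-co-occurring pairs at the positives' step.

    Rejects self-pairs and pairs present in E_t (and, optionally, any
    historical pair).  Deterministic under a fixed seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if graph.n_concepts < 3:
        raise ValueError("vocabulary too small for negative sampling")
    if not positives:
        return []
    t = positives[0].t
    if any(p.t != t for p in positives):
        raise ValueError("positives must share one target step")
    forbidden = {e.pair for e in graph.events_at(t)}
    if exclude_history:
        forbidden |= graph.pairs_before(t)
    n_needed = math.ceil(ratio * len(positives))
    if rng is None:
        rng = np.random.default_rng(seed)
    out: list[PairSample] = []
    n = graph.n_concepts
    tries = 0
    max_tries = 1000 * n_needed + 10000
    while len(out) < n_needed:
        if tries >= max_tries:
            raise RuntimeError(
                "negative sampling exceeded rejection budget; graph too dense"
            )
        tries += 1
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        pair = (min(i, j), max(i, j))
        if pair in forbidden:
            continue
        out.append(PairSample(int(i), int(j), t, 0))
    return out


# ---------------------------------------------------------------------------
# edge-event file round trip


def write_edge_events(graph: TemporalGraph, prefix) -> tuple[Path, Path]:
    """Write PREFIX.events.tsv and PREFIX.vocab.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vocab_path = Path(str(prefix) + ".vocab.tsv")
    events_path = Path(str(prefix) + ".events.tsv")
    with open(vocab_path, "w", encoding="utf-8") as fh:
        for cid, name in zip(graph.concepts, graph.names):
            fh.write(f"{cid}\t{name}\n")
    with open(events_path, "w", encoding="utf-8") as fh:
        fh.write(f"# horizon: {graph.horizon}\n")
        for e in graph.events:
            fh.write(f"{e.t}\t{graph.concepts[e.i]}\t{graph.concepts[e.j]}\n")
    return events_path, vocab_path


def read_edge_events(prefix) -> TemporalGraph:
    """Inverse of :func:`write_edge_events`; round-trip is identity."""
    prefix = Path(prefix)
    vocab_path = Path(str(prefix) + ".vocab.tsv")
    events_path = Path(str(prefix) + ".events.tsv")
    concepts: list[str] = []
    names: list[str] = []
    with open(vocab_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{vocab_path}:{lineno}: expected 2 columns")
            concepts.append(cols[0])
            names.append(cols[1])
    index = {cid: k for k, cid in enumerate(concepts)}
    horizon: int | None = None
    events: list[EdgeEvent] = []
    with open(events_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "horizon:" in line:
                    horizon = int(line.split("horizon:")[1])
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ValueError(f"{events_path}:{lineno}: expected 3 columns")
            t = int(cols[0])
            if t < 1:
                raise ValueError(
                    f"{events_path}:{lineno}: step {t} invalid (E0 is empty)"
                )
            for cid in cols[1:]:
                if cid not in index:
                    raise ValueError(
                        f"{events_path}:{lineno}: unknown concept id {cid!r}"
                    )
            events.append(EdgeEvent(t, index[cols[1]], index[cols[2]]))
    if horizon is None:
        horizon = max((e.t for e in events), default=0)
    return TemporalGraph(concepts, horizon, events, names)
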