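import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conceptdrift.events import (
    AnnotationRecord,
    EdgeEvent,
    PairSample,
    SplitSpec,
    TemporalGraph,
    build_temporal_graph,
    filter_annotations,
    neighborhood,
    parse_annotations,
    read_edge_events,
    remove_seen_pairs,
    sample_negatives,
    write_edge_events,
)


class TestParse:
    def test_reads_records_in_order(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "P1\t2000\tD1\tMeSH\tone\n"
            "P2\t2001\tD2\tMeSH\ttwo\n"
            "P3\t2002\tD3\tMeSH\tthree\n"
        )
        recs = parse_annotations(p)
        assert [r.article_id for r in recs] == ["P1", "P2", "P3"]
        assert recs[1] == AnnotationRecord("P2", 2001, "D2", "MeSH", "two")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("")
        assert parse_annotations(p) == []

    def test_malformed_line_skipped_and_reported(self, tmp_path, caplog):
        lines = [f"P{k}\t2000\tD{k}\tMeSH\tname{k}" for k in range(10)]
        lines.insert(4, "broken\tline\twith\tfour")
        p = tmp_path / "a.tsv"
        p.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            recs = parse_annotations(p)
        assert len(recs) == 10
        assert "5" in caplog.text  # 1-based line number of the bad line

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(OSError):
            parse_annotations(tmp_path / "nope.tsv")


class TestFilter:
    def test_blank_concept_id_dropped(self):
        r = AnnotationRecord("P", 2000, "", "MeSH", "x")
        assert filter_annotations([r]) == []

    def test_non_mesh_type_dropped(self):
        r = AnnotationRecord("P", 2000, "G1", "Gene", "x")
        assert filter_annotations([r]) == []

    def test_mesh_record_retained_and_order_preserved(self):
        keep1 = AnnotationRecord("P", 2000, "D010300", "MeSH", "x")
        drop = AnnotationRecord("P", 2000, " ", "MeSH", "y")
        keep2 = AnnotationRecord("P", 2000, "D2", "MeSH", "z")
        assert filter_annotations([keep1, drop, keep2]) == [keep1, keep2]

    def test_custom_tag(self):
        r = AnnotationRecord("P", 2000, "X1", "Chemical", "x")
        assert filter_annotations([r], mesh_tag="Chemical") == [r]


class TestBuild:
    def test_pairwise_combinations_single_article(self):
        recs = [
            AnnotationRecord("P1", 2000, c, "MeSH", c) for c in ("a", "b", "c")
        ]
        g = build_temporal_graph(recs, 2000, 2001)
        assert g.horizon == 2
        assert {(e.i, e.j, e.t) for e in g.events} == {(0, 1, 1), (0, 2, 1), (1, 2, 1)}

    def test_single_concept_article_yields_no_events(self):
        recs = [AnnotationRecord("P1", 2000, "a", "MeSH", "a")]
        g = build_temporal_graph(recs, 2000, 2000)
        assert g.events == []

    def test_same_year_duplicates_collapse(self):
        recs = [
            AnnotationRecord(pid, 2000, c, "MeSH", c)
            for pid in ("P1", "P2")
            for c in ("a", "b")
        ]
        g = build_temporal_graph(recs, 2000, 2000)
        assert len(g.events) == 1

    def test_year_out_of_range_fatal(self):
        recs = [AnnotationRecord("P1", 1999, "a", "MeSH", "a")]
        with pytest.raises(ValueError, match="1999"):
            build_temporal_graph(recs, 2000, 2001)

    def test_step_zero_reserved(self):
        recs = [
            AnnotationRecord("P1", 2000, c, "MeSH", c) for c in ("a", "b")
        ]
        g = build_temporal_graph(recs, 2000, 2000)
        assert g.events[0].t == 1 and g.events_at(0) == []


class TestNeighborhood:
    def make(self):
        return TemporalGraph(
            ["a", "b", "c", "d"], 3, [EdgeEvent(1, 0, 1), EdgeEvent(2, 0, 2)]
        )

    def test_cumulative(self):
        g = self.make()
        assert neighborhood(g, 0, 2) == {1, 2}

    def test_intermediate_step(self):
        g = self.make()
        assert neighborhood(g, 0, 1) == {1}

    def test_step_zero_empty(self):
        g = self.make()
        assert neighborhood(g, 0, 0) == set()

    def test_out_of_range_fatal(self):
        g = self.make()
        with pytest.raises(IndexError):
            neighborhood(g, 9, 1)

    @given(st.lists(
        st.tuples(st.integers(1, 4), st.integers(0, 5), st.integers(0, 5)),
        max_size=30,
    ))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_t(self, raw):
        events = [EdgeEvent(t, i, j) for t, i, j in raw if i != j]
        g = TemporalGraph([str(k) for k in range(6)], 4, events)
        for i in range(6):
            for t in range(4):
                assert neighborhood(g, i, t) <= neighborhood(g, i, t + 1)


class TestLeakage:
    def test_historical_pair_removed(self, toy_graph):
        out = remove_seen_pairs({(0, 1), (3, 4)}, toy_graph, 4)
        assert out == {(3, 4)}

    def test_empty_history(self):
        g = TemporalGraph(["a", "b", "c"], 2, [])
        cands = {(0, 1), (1, 2)}
        assert remove_seen_pairs(cands, g, 2) == cands

    def test_all_candidates_historical(self, toy_graph):
        assert remove_seen_pairs({(0, 1), (0, 2)}, toy_graph, 4) == set()

    def test_brute_force_no_leftovers(self, toy_graph):
        all_pairs = set(itertools.combinations(range(5), 2))
        for before in range(1, 5):
            out = remove_seen_pairs(all_pairs, toy_graph, before)
            seen = {e.pair for e in toy_graph.events if e.t < before}
            assert out & seen == set()
            assert out | seen == all_pairs


class TestNegatives:
    def positives(self, toy_graph, t=4):
        return [PairSample(e.i, e.j, t, 1) for e in toy_graph.events_at(t)]

    def test_counts_and_purity(self, toy_graph):
        pos = self.positives(toy_graph)
        negs = sample_negatives(pos * 5, toy_graph, ratio=1.0, seed=1)
        assert len(negs) == 5
        present = {e.pair for e in toy_graph.events_at(4)}
        for s in negs:
            assert s.label == 0 and s.i != s.j and s.pair not in present

    def test_deterministic_under_seed(self, toy_graph):
        pos = self.positives(toy_graph)
        a = sample_negatives(pos, toy_graph, seed=7)
        b = sample_negatives(pos, toy_graph, seed=7)
        assert a == b

    def test_ratio_two(self, toy_graph):
        pos = self.positives(toy_graph) * 3
        negs = sample_negatives(pos, toy_graph, ratio=2.0, seed=0)
        assert len(negs) == 6

    def test_exclude_history_flag(self, toy_graph):
        pos = self.positives(toy_graph) * 30
        negs = sample_negatives(pos, toy_graph, seed=0, exclude_history=True)
        historical = toy_graph.pairs_before(4)
        assert all(s.pair not in historical for s in negs)

    def test_dense_graph_fatal(self):
        events = [EdgeEvent(1, i, j) for i, j in itertools.combinations(range(3), 2)]
        g = TemporalGraph(["a", "b", "c"], 1, events)
        pos = [PairSample(e.i, e.j, 1, 1) for e in events]
        with pytest.raises(RuntimeError):
            sample_negatives(pos, g, seed=0)


class TestRoundTrip:
    def test_round_trip_identity(self, toy_graph, tmp_path):
        write_edge_events(toy_graph, tmp_path / "g")
        assert read_edge_events(tmp_path / "g") == toy_graph

    def test_event_at_step_zero_rejected(self, tmp_path):
        (tmp_path / "g.vocab.tsv").write_text("a\ta\nb\tb\n")
        (tmp_path / "g.events.tsv").write_text("0\ta\tb\n")
        with pytest.raises(ValueError, match="E0"):
            read_edge_events(tmp_path / "g")

    def test_unknown_concept_fatal(self, tmp_path):
        (tmp_path / "g.vocab.tsv").write_text("a\ta\nb\tb\n")
        (tmp_path / "g.events.tsv").write_text("1\ta\tzzz\n")
        with pytest.raises(ValueError, match="zzz"):
            read_edge_events(tmp_path / "g")


class TestInvariants:
    def test_event_canonical_and_dedup(self):
        g = TemporalGraph(["a", "b"], 1, [EdgeEvent(1, 1, 0), EdgeEvent(1, 0, 1)])
        assert g.events == [EdgeEvent(1, 0, 1)]

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError):
            EdgeEvent(1, 2, 2)

    def test_split_spec_ordering(self):
        with pytest.raises(ValueError):
            SplitSpec(5, 5, 6)
        s = SplitSpec(3, 4, 5)
        assert s.train_end == 3

    def test_negative_sample_requires_three_concepts(self):
        g = TemporalGraph(["a", "b"], 1, [])
        with pytest.raises(ValueError):
            sample_negatives([PairSample(0, 1, 1, 1)], g, seed=0)
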