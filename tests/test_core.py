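"""Predication I/O, deduplication, graph construction, temporal splitting."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from litkg import core
from litkg.core import Predication, Triple


def test_predication_requires_key_fields():
    with pytest.raises(ValueError):
        Predication("", "TREATS", "C1")
    with pytest.raises(ValueError):
        Predication("C1", "TREATS", "")
    with pytest.raises(ValueError):
        Predication("C1", "TREATS", "C2", year=-3)


class TestReadWrite:
    def test_identity_read(self, tmp_path, small_corpus):
        path = tmp_path / "p.csv"
        assert core.write_predications(small_corpus[:3], path) == 3
        assert core.read_predications(path) == small_corpus[:3]

    def test_empty_write_has_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        assert core.write_predications([], path) == 0
        assert path.read_text().strip() == ",".join(core.SEMMEDDB_DIALECT.values())
        assert core.read_predications(path) == []

    def test_row_missing_object_skipped(self, tmp_path, caplog):
        path = tmp_path / "p.csv"
        path.write_text(
            "SUBJECT_CUI,SUBJECT_NAME,SUBJECT_SEMTYPE,PREDICATE,OBJECT_CUI,"
            "OBJECT_NAME,OBJECT_SEMTYPE,PMID,YEAR,SENTENCE\n"
            "C1,a,phsu,TREATS,C2,b,dsyn,1,2010,s\n"
            "C1,a,phsu,TREATS,,b,dsyn,2,2011,s\n"
        )
        with caplog.at_level(logging.WARNING):
            recs = core.read_predications(path)
        assert len(recs) == 1
        assert "skipped 1" in caplog.text

    def test_unparseable_year_kept_as_missing(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "SUBJECT_CUI,PREDICATE,OBJECT_CUI,YEAR,SUBJECT_NAME,SUBJECT_SEMTYPE,"
            "OBJECT_NAME,OBJECT_SEMTYPE,PMID,SENTENCE\n"
            "C1,TREATS,C2,circa-2010,a,phsu,b,dsyn,1,s\n"
        )
        (rec,) = core.read_predications(path)
        assert rec.year is None

    def test_missing_file_is_fatal(self):
        with pytest.raises(OSError):
            core.read_predications("/no/such/file.csv")

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(
        st.builds(
            Predication,
            subject_id=st.from_regex(r"C[0-9]{4}", fullmatch=True),
            predicate=st.sampled_from(["TREATS", "PREVENTS", "AFFECTS"]),
            object_id=st.from_regex(r"C[0-9]{4}", fullmatch=True),
            subject_name=st.text(alphabet="abc xyz", max_size=8),
            year=st.one_of(st.none(), st.integers(1900, 2030)),
            sentence=st.text(alphabet="abc. xyz", max_size=20),
        ),
        max_size=20,
    ))
    def test_round_trip(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("rt") / "p.csv"
        core.write_predications(records, path)
        assert core.read_predications(path) == records


class TestDeduplicate:
    def test_merges_years_to_min(self, small_corpus):
        triples = core.deduplicate(small_corpus[:3])
        assert triples == [Triple("C001", "TREATS", "C100", 2010)]

    def test_predicate_distinguishes(self):
        recs = [Predication("A", "TREATS", "B", year=2010),
                Predication("A", "PREVENTS", "B", year=2011)]
        assert len(core.deduplicate(recs)) == 2

    def test_all_missing_years_stay_missing(self):
        recs = [Predication("A", "TREATS", "B"), Predication("A", "TREATS", "B")]
        (t,) = core.deduplicate(recs)
        assert t.first_year is None

    def test_random_multiset_matches_groupby_oracle(self):
        rng = np.random.default_rng(7)
        recs = [
            Predication(f"C{rng.integers(5)}", "R", f"C{rng.integers(5)}",
                        year=int(rng.integers(2000, 2020)))
            for _ in range(200)
        ]
        expected = {}
        for r in recs:
            expected[r.key] = min(expected.get(r.key, 9999), r.year)
        got = core.deduplicate(recs)
        assert len(got) == len(expected)
        assert {t.key: t.first_year for t in got} == expected

    def test_idempotent(self, small_corpus):
        once = core.deduplicate(small_corpus)
        lifted = [Predication(t.head, t.relation, t.tail, year=t.first_year) for t in once]
        assert core.deduplicate(lifted) == once


class TestBuildGraph:
    def test_adjacency_counts_distinct_triples(self):
        g = core.build_graph([Triple("A", "R1", "B"), Triple("A", "R2", "B")])
        a, b = g.entity_index["A"], g.entity_index["B"]
        assert g.adjacency == {(a, b): 2}

    def test_binary_adjacency_clips(self):
        g = core.build_graph([Triple("A", "R1", "B"), Triple("A", "R2", "B")],
                             binary_adjacency=True)
        assert set(g.adjacency.values()) == {1}

    def test_empty_graph(self):
        g = core.build_graph([])
        assert g.n_entities == g.n_relations == 0 and g.adjacency == {}

    def test_duplicate_triple_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            core.build_graph([Triple("A", "R", "B", 2000), Triple("A", "R", "B", 2001)])

    def test_indices_gap_free_and_adjacency_sums(self, synth_corpus):
        _, preds, _ = synth_corpus
        triples = core.deduplicate(preds)
        g = core.build_graph(triples)
        assert sorted(g.entity_index.values()) == list(range(g.n_entities))
        assert sorted(g.relation_index.values()) == list(range(g.n_relations))
        assert sum(g.adjacency.values()) == len(triples)
        # row/col sums equal per-entity out/in triple counts (brute force)
        out_counts = np.zeros(g.n_entities)
        in_counts = np.zeros(g.n_entities)
        for t in triples:
            out_counts[g.entity_index[t.head]] += 1
            in_counts[g.entity_index[t.tail]] += 1
        row = np.zeros(g.n_entities)
        col = np.zeros(g.n_entities)
        for (h, t), c in g.adjacency.items():
            row[h] += c
            col[t] += c
        assert np.array_equal(row, out_counts) and np.array_equal(col, in_counts)

    def test_graph_round_trip(self, small_corpus):
        triples = core.deduplicate(small_corpus)
        g = core.build_graph(triples)
        assert set(t.key for t in g.triples) == set(t.key for t in triples)


class TestTemporalSplit:
    def test_boundary_semantics(self):
        ts = [Triple("A", "R", "B", 2015), Triple("B", "R", "C", 2019),
              Triple("C", "R", "D", 2021)]
        s = core.temporal_split(ts, 2019, 2020)
        assert [t.first_year for t in s.train] == [2015]
        assert [t.first_year for t in s.validation] == [2019]
        assert [t.first_year for t in s.test] == [2021]

    def test_all_past_leaves_later_slices_empty(self):
        ts = [Triple("A", "R", "B", 2001), Triple("B", "R", "C", 2002)]
        s = core.temporal_split(ts, 2019, 2020)
        assert len(s.train) == 2 and not s.validation and not s.test

    def test_invalid_boundaries(self):
        with pytest.raises(ValueError):
            core.temporal_split([], 2022, 2020)

    def test_partition_conservation_and_bucket_oracle(self):
        rng = np.random.default_rng(3)
        ts = [Triple(f"A{i}", "R", f"B{i}",
                     None if rng.random() < 0.1 else int(rng.integers(2000, 2025)))
              for i in range(500)]
        s = core.temporal_split(ts, 2019, 2020)
        assert len(s.train) + len(s.validation) + len(s.test) + s.n_excluded_missing_year == len(ts)
        years = [t.first_year for t in ts if t.first_year is not None]
        assert len(s.train) == sum(y < 2019 for y in years)
        assert len(s.validation) == sum(2019 <= y <= 2020 for y in years)
        assert len(s.test) == sum(y > 2020 for y in years)
        assert all(t.first_year < 2019 for t in s.train)


def test_triples_tsv_round_trip(tmp_path, small_corpus):
    triples = core.deduplicate(small_corpus)
    path = tmp_path / "t.tsv"
    assert core.triples_to_tsv(triples, path) == len(triples)
    assert core.triples_from_tsv(path) == triples
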