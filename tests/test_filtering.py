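"""Semantic blocklist, degree centrality, G² association, composite top-k filter."""

import numpy as np
import pytest

from litkg import core, filtering
from litkg.core import Predication, Triple

GROUP_MAP = {"phsu": "Chemicals & Drugs", "dsyn": "Disorders",
             "idcn": "Concepts & Ideas", "acty": "Activities & Behaviors",
             "orch": "Chemicals & Drugs", "phsf": "Physiology", "mobd": "Disorders"}


class TestSemanticTypeFilter:
    def test_blocked_group_removes_record(self, small_corpus):
        retained, removed = filtering.semantic_type_filter(
            small_corpus, {"Concepts & Ideas"}, GROUP_MAP)
        assert removed == 1
        assert all(GROUP_MAP.get(r.subject_semtype) != "Concepts & Ideas" for r in retained)
        assert len(retained) + removed == len(small_corpus)

    def test_empty_blocklist_is_identity(self, small_corpus):
        retained, removed = filtering.semantic_type_filter(small_corpus, set(), GROUP_MAP)
        assert retained == small_corpus and removed == 0

    def test_unmapped_semtype_passes_through(self):
        rec = Predication("C1", "TREATS", "C2", subject_semtype="zzzz")
        retained, removed = filtering.semantic_type_filter([rec], {"Disorders"}, GROUP_MAP)
        assert retained == [rec]

    def test_matches_per_record_oracle(self):
        rng = np.random.default_rng(11)
        semtypes = list(GROUP_MAP)
        recs = [Predication(f"C{i}", "R", f"D{i}",
                            subject_semtype=semtypes[rng.integers(len(semtypes))],
                            object_semtype=semtypes[rng.integers(len(semtypes))])
                for i in range(100)]
        blocklist = {"Concepts & Ideas", "Physiology"}
        retained, removed = filtering.semantic_type_filter(recs, blocklist, GROUP_MAP)
        expect = [r for r in recs
                  if GROUP_MAP[r.subject_semtype] not in blocklist
                  and GROUP_MAP[r.object_semtype] not in blocklist]
        assert retained == expect and removed == len(recs) - len(expect)


class TestDegreeCentrality:
    def test_symmetric_two_cycle(self):
        g = core.build_graph([Triple("A", "R", "B"), Triple("B", "R", "A")])
        c = filtering.degree_centrality(g)
        assert np.array_equal(c.a_in, [1, 1]) and np.array_equal(c.a_out, [1, 1])

    def test_directed_counts(self):
        g = core.build_graph([Triple("A", "R1", "B"), Triple("A", "R2", "B")])
        c = filtering.degree_centrality(g)
        a, b = g.entity_index["A"], g.entity_index["B"]
        assert c.a_out[a] == 2 and c.a_out[b] == 0
        assert c.a_in[a] == 0 and c.a_in[b] == 2

    def test_matches_dense_matrix_oracle(self, synth_corpus):
        _, preds, _ = synth_corpus
        g = core.build_graph(core.deduplicate(preds))
        c = filtering.degree_centrality(g)
        M = np.zeros((g.n_entities, g.n_entities))
        for (h, t), v in g.adjacency.items():
            M[h, t] = v
        assert np.allclose(c.a_out, M.sum(axis=1))
        assert np.allclose(c.a_in, M.sum(axis=0))
        assert c.a_in.sum() == c.a_out.sum() == sum(g.adjacency.values())


class TestIndependenceExpectation:
    def test_uniform_table_unchanged(self):
        t = filtering.independence_expectation(np.full((2, 2), 5.0))
        assert np.allclose(t.expected, 5.0)

    def test_hand_computed_marginals(self):
        t = filtering.independence_expectation(np.array([[10.0, 20.0], [30.0, 40.0]]))
        assert np.allclose(t.expected, [[12, 18], [28, 42]])

    def test_expected_sums_to_total_any_rank(self):
        rng = np.random.default_rng(5)
        for shape in [(2, 2), (2, 3), (2, 2, 2), (3, 4, 2)]:
            O = rng.integers(0, 30, size=shape).astype(float)
            if O.sum() == 0:
                continue
            t = filtering.independence_expectation(O)
            assert np.isclose(t.expected.sum(), O.sum(), rtol=1e-9)

    def test_rank_one_structure_is_fixed_point(self):
        rows, cols = np.array([3.0, 7.0]), np.array([4.0, 6.0])
        O = np.outer(rows, cols) / 10.0
        t = filtering.independence_expectation(O)
        assert np.allclose(t.expected, O)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            filtering.independence_expectation(np.zeros((2, 2)))


class TestGSquared:
    def test_exact_independence_is_zero(self):
        t = filtering.independence_expectation(np.outer([3.0, 7.0], [4.0, 6.0]))
        assert filtering.g_squared(t) == 0.0

    def test_frozen_2x2_value(self):
        # 2*(10 ln(10/12) + 20 ln(20/18) + 30 ln(30/28) + 40 ln(40/42))
        t = filtering.independence_expectation(np.array([[10.0, 20.0], [30.0, 40.0]]))
        assert filtering.g_squared(t) == pytest.approx(0.804349, abs=1e-5)

    def test_zero_observed_cells_contribute_nothing(self):
        t = filtering.independence_expectation(np.array([[0.0, 10.0], [10.0, 10.0]]))
        val = filtering.g_squared(t)
        assert np.isfinite(val) and val > 0

    def test_observed_without_expectation_is_error(self):
        t = filtering.ContingencyTable(np.array([1.0, 1.0]), np.array([0.0, 2.0]), 2.0)
        with pytest.raises(ValueError):
            filtering.g_squared(t)

    def test_matches_scipy_log_likelihood_ratio(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(9)
        for _ in range(50):
            O = rng.integers(1, 40, size=(2, 2)).astype(float)
            ours = filtering.g_squared(filtering.independence_expectation(O))
            theirs = chi2_contingency(O, correction=False,
                                      lambda_="log-likelihood").statistic
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_transposition_invariance_and_count_scaling(self):
        rng = np.random.default_rng(13)
        O = rng.integers(1, 30, size=(2, 3)).astype(float)
        g = filtering.g_squared(filtering.independence_expectation(O))
        gt = filtering.g_squared(filtering.independence_expectation(O.T))
        assert g == pytest.approx(gt, rel=1e-12)
        for c in (2, 5):
            gc = filtering.g_squared(filtering.independence_expectation(c * O))
            assert gc == pytest.approx(c * g, rel=1e-12)


class TestPairAssociation:
    def test_perfect_association_dominates(self):
        recs = ([Predication("S", "R", "O")] * 6
                + [Predication(f"X{i}", "R", f"Y{j}") for i in range(3) for j in range(3)])
        g2 = filtering.pair_association(recs)
        assert max(g2, key=g2.get) == ("S", "O")

    def test_independent_pair_scores_zero(self):
        # s co-occurs with o at exactly the independence rate
        recs = ([Predication("s", "R", "o")] * 1 + [Predication("s", "R", "q")] * 1
                + [Predication("p", "R", "o")] * 1 + [Predication("p", "R", "q")] * 1)
        g2 = filtering.pair_association(recs)
        assert g2[("s", "o")] == pytest.approx(0.0, abs=1e-12)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(21)
        recs = [Predication(f"S{rng.integers(4)}", "R", f"O{rng.integers(4)}")
                for _ in range(200)]
        g2 = filtering.pair_association(recs)
        n = len(recs)
        for (s, o), val in g2.items():
            n_so = sum(1 for r in recs if r.subject_id == s and r.object_id == o)
            n_s = sum(1 for r in recs if r.subject_id == s)
            n_o = sum(1 for r in recs if r.object_id == o)
            O = np.array([[n_so, n_s - n_so], [n_o - n_so, n - n_s - n_o + n_so]], float)
            expect = filtering.g_squared(filtering.independence_expectation(O))
            assert val == pytest.approx(expect, rel=1e-12)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            filtering.pair_association([])


def _score_fixture():
    triples = [Triple("A", "R", "B"), Triple("C", "R", "D")]
    raw = np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
    norm = np.column_stack([filtering._minmax(raw[:, j]) for j in range(3)])
    return filtering.TripleScoreTable(triples, raw, norm, norm.sum(axis=1))


class TestCompositeScores:
    def test_single_triple_degenerates_to_zero(self):
        recs = [Predication("A", "R", "B")]
        triples = core.deduplicate(recs)
        g = core.build_graph(triples)
        scores = filtering.composite_scores(
            triples, filtering.degree_centrality(g), filtering.pair_association(recs))
        assert scores.composite.tolist() == [0.0]

    def test_min_max_endpoints(self):
        scores = _score_fixture()
        assert scores.composite.tolist() == [0.0, 3.0]

    def test_components_in_unit_interval_and_ordering_oracle(self, synth_corpus):
        _, preds, _ = synth_corpus
        preds = preds[:500]
        triples = core.deduplicate(preds)
        g = core.build_graph(triples)
        cent = filtering.degree_centrality(g)
        assoc = filtering.pair_association(preds)
        scores = filtering.composite_scores(triples, cent, assoc)
        assert np.all(scores.normalized >= 0) and np.all(scores.normalized <= 1)
        assert np.all(scores.composite <= 3 + 1e-12)
        # brute-force recomputation of the composite ordering
        raw = np.array([[cent.a_out_of(t.head), cent.a_in_of(t.tail),
                         assoc[(t.head, t.tail)]] for t in triples])
        comp = np.zeros(len(triples))
        for j in range(3):
            lo, hi = raw[:, j].min(), raw[:, j].max()
            if hi > lo:
                comp += (raw[:, j] - lo) / (hi - lo)
        assert np.argsort(-comp).tolist() == np.argsort(-scores.composite).tolist()

    def test_missing_lookup_is_error(self):
        scores = _score_fixture()
        cent = filtering.CentralityTable(np.zeros(1), np.zeros(1), {"A": 0})
        with pytest.raises(KeyError):
            filtering.composite_scores([Triple("A", "R", "Z")], cent, {})


class TestSelectTopK:
    def test_whitelist_overrides_k(self):
        scores = _score_fixture()
        kept = filtering.select_top_k(scores.triples, scores, 0,
                                      whitelist={"B", "D"})
        assert len(kept) == 2

    def test_full_k_empty_whitelist_is_identity(self):
        scores = _score_fixture()
        kept = filtering.select_top_k(scores.triples, scores, 2, set())
        assert set(t.key for t in kept) == set(t.key for t in scores.triples)

    def test_matches_sort_slice_oracle_and_monotone(self):
        rng = np.random.default_rng(31)
        triples = [Triple(f"H{i}", "R", f"T{i}") for i in range(40)]
        raw = rng.random((40, 3))
        norm = np.column_stack([filtering._minmax(raw[:, j]) for j in range(3)])
        scores = filtering.TripleScoreTable(triples, raw, norm, norm.sum(axis=1))
        prev: set = set()
        for k in range(0, 41, 5):
            kept = filtering.select_top_k(triples, scores, k, set())
            order = sorted(zip(scores.composite, triples),
                           key=lambda st: (-st[0], st[1].key))
            assert [t.key for t in kept] == [t.key for _, t in order[:k]]
            keys = {t.key for t in kept}
            assert prev <= keys  # increasing k never drops a triple
            prev = keys
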