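"""Link-prediction evaluation: MR, MRR, Hits@k, and the time-slicing harness.

For each test triple the true head (and/or tail) is ranked against every
candidate entity by model score.  Ties share the mean rank of their block,
so an all-tied candidate list of size n yields rank (n+1)/2 rather than an
enumeration-order artifact.  The *filtered* protocol removes candidates that
would form another known-true triple before ranking; *raw* keeps them.

Time-slicing trains only on triples first published before a cutoff year and
evaluates on triples that first appear later — the standard literature-mining
check that a model predicts genuinely new assertions rather than re-scoring
old ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import models as M
from .core import Triple, build_graph, deduplicate, temporal_split


@dataclass
class RankingMetrics:
    """Aggregate ranking quality over a set of queries."""

    mr: float
    mrr: float
    hits: dict[int, float]
    n_queries: int
    protocol: str = "filtered"
    sides: str = "both"

    def as_row(self) -> dict[str, float]:
        row = {"MR": self.mr, "MRR": self.mrr}
        for k in sorted(self.hits):
            row[f"Hits@{k}"] = self.hits[k]
        return row


def rank_query(
    model: M.EmbeddingModel,
    triple: tuple[int, int, int],
    side: str,
    protocol: str = "filtered",
    known_triples: Iterable[tuple[int, int, int]] | None = None,
) -> float:
    """Rank of the true entity among all candidate substitutions of one side.

    rank = 1 + (#candidates scoring strictly higher) + (#exact ties)/2.
    Under ``protocol="filtered"`` candidates forming a known true triple
    (other than the query itself) are removed first.
    """
    if protocol not in ("raw", "filtered"):
        raise ValueError("protocol must be 'raw' or 'filtered'")
    h, r, t = triple
    true_ent = h if side == "head" else t
    fixed = t if side == "head" else h
    scores = M.score_candidates(model, r, fixed, side)
    mask = np.ones(model.n_entities, dtype=bool)
    if protocol == "filtered" and known_triples is not None:
        for kh, kr, kt in known_triples:
            if side == "head" and kr == r and kt == t and kh != true_ent:
                mask[kh] = False
            elif side == "tail" and kr == r and kh == h and kt != true_ent:
                mask[kt] = False
    true_score = scores[true_ent]
    cand = scores[mask]
    higher = int(np.sum(cand > true_score))
    ties = int(np.sum(cand == true_score)) - 1  # the true entity ties itself
    return 1.0 + higher + ties / 2.0


def evaluate(
    model: M.EmbeddingModel,
    test_triples: Sequence[tuple[int, int, int]],
    known_triples: Iterable[tuple[int, int, int]] | None = None,
    ks: Sequence[int] = (1, 3, 10),
    protocol: str = "filtered",
    sides: str = "both",
) -> RankingMetrics:
    """MR / MRR / Hits@k over head- and/or tail-corruption queries.

    With ``sides="both"`` each test triple contributes one head query and one
    tail query.  ``known_triples`` should contain every triple regarded as
    true (train + valid + test) for the filtered protocol.
    """
    if not len(test_triples):
        raise ValueError("evaluate requires a non-empty test set")
    side_list = ("head", "tail") if sides == "both" else (sides,)
    known = _index_known(known_triples) if (protocol == "filtered" and known_triples is not None) else None
    ranks = []
    for triple in test_triples:
        for side in side_list:
            if known is not None:
                h, r, t = triple
                rel = known.get((r, t), ()) if side == "head" else known.get((r, h, "t"), ())
                ranks.append(_rank_with_prefiltered(model, triple, side, rel))
            else:
                ranks.append(rank_query(model, triple, side, "raw", None))
    ranks = np.asarray(ranks)
    hits = {k: float(np.mean(ranks <= k)) for k in ks}
    return RankingMetrics(
        mr=float(ranks.mean()),
        mrr=float((1.0 / ranks).mean()),
        hits=hits,
        n_queries=len(ranks),
        protocol=protocol,
        sides=sides,
    )


def _index_known(known_triples: Iterable[tuple[int, int, int]]):
    """Index known triples for fast filtered ranking.

    Head queries for (?, r, t) must drop known heads of (r, t); tail queries
    for (h, r, ?) must drop known tails of (h, r).
    """
    idx: dict = {}
    for h, r, t in known_triples:
        idx.setdefault((r, t), []).append(h)
        idx.setdefault((r, h, "t"), []).append(t)
    return idx


def _rank_with_prefiltered(model, triple, side, remove_ids) -> float:
    h, r, t = triple
    true_ent = h if side == "head" else t
    fixed = t if side == "head" else h
    scores = M.score_candidates(model, r, fixed, side)
    mask = np.ones(model.n_entities, dtype=bool)
    if len(remove_ids):
        mask[np.asarray(remove_ids, dtype=int)] = False
    mask[true_ent] = True
    true_score = scores[true_ent]
    cand = scores[mask]
    higher = int(np.sum(cand > true_score))
    ties = int(np.sum(cand == true_score)) - 1
    return 1.0 + higher + ties / 2.0


@dataclass
class TimeSliceResult:
    """Outcome of a full time-sliced train/evaluate run."""

    model: M.EmbeddingModel
    loss_trace: list[float]
    validation: RankingMetrics | None
    test: RankingMetrics
    n_train: int
    n_validation: int
    n_test: int
    entity_index: dict[str, int]
    relation_index: dict[str, int]


def time_slice_evaluate(
    predications,
    train_before: int,
    valid_through: int,
    family: str,
    config: M.TrainConfig,
    protocol: str = "filtered",
    ks: Sequence[int] = (1, 3, 10),
) -> TimeSliceResult:
    """Dedup, split on first publication year, train on the past, score the future.

    The graph is indexed over all split triples so that later slices are
    scoreable, but only training-slice triples reach the optimizer; the
    absence of train/test leakage is asserted.  Validation/test triples whose
    head or tail never appears in training are dropped from evaluation (their
    embeddings are untrained noise).
    """
    triples = deduplicate(predications)
    split = temporal_split(triples, train_before, valid_through)
    if not split.train or not split.test:
        raise ValueError(
            f"degenerate temporal split: {len(split.train)} train / {len(split.test)} test triples"
        )
    assert not (set(t.key for t in split.train) & set(t.key for t in split.test))
    graph = build_graph(split.train + split.validation + split.test)
    e, r = graph.entity_index, graph.relation_index

    def ids(ts: Sequence[Triple]) -> list[tuple[int, int, int]]:
        return [(e[t.head], r[t.relation], e[t.tail]) for t in ts]

    train_ids = ids(split.train)
    model, trace = M.train(train_ids, family, graph.n_entities, graph.n_relations, config)
    train_ents = {i for h, _, t in train_ids for i in (h, t)}
    known = ids(triples)

    def metrics_for(ts: Sequence[Triple]) -> RankingMetrics | None:
        eligible = [q for q in ids(ts) if q[0] in train_ents and q[2] in train_ents]
        if not eligible:
            return None
        return evaluate(model, eligible, known, ks=ks, protocol=protocol)

    test_metrics = metrics_for(split.test)
    if test_metrics is None:
        raise ValueError("no test triple has both endpoints in the training slice")
    return TimeSliceResult(
        model=model,
        loss_trace=trace,
        validation=metrics_for(split.validation),
        test=test_metrics,
        n_train=len(split.train),
        n_validation=len(split.validation),
        n_test=len(split.test),
        entity_index=e,
        relation_index=r,
    )


def random_hits_baseline(k: int, n_entities: int) -> float:
    """Expected Hits@k of a uniformly random ranking over n-1 candidates."""
    return min(1.0, k / (n_entities - 1))


def metrics_to_csv(metrics: RankingMetrics, path: str) -> None:
    """One-row CSV in the conventional column order MR, MRR, Hits@1, Hits@3, Hits@10."""
    import csv

    row = metrics.as_row()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(row.keys())
        w.writerow([f"{v:.4f}" for v in row.values()])
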