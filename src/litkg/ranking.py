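"""Repurposing candidate ranking.

Given a trained embedding model, every (category head, relation, disease
tail) triple is enumerated and scored; triples are ranked per (relation,
tail) list, and entities are ranked by how many of those per-list top-N
slots they occupy.  Drug and chemical categories default to the TREATS and
PREVENTS relations; dietary supplements to AFFECTS, where direct
treatment links are rarely asserted in the literature.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import models as M

logger = logging.getLogger(__name__)

DEFAULT_RELATIONS = {
    "drug": {"TREATS", "PREVENTS"},
    "chemical": {"TREATS", "PREVENTS"},
    "supplement": {"AFFECTS"},
}


@dataclass
class CandidateCategory:
    """A head-concept category and the relations it is scored over."""

    name: str
    head_ids: set[str]
    relations: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.head_ids:
            raise ValueError("category head_ids must be non-empty")
        if not self.relations:
            self.relations = set(DEFAULT_RELATIONS.get(self.name, {"TREATS", "PREVENTS"}))


@dataclass(frozen=True)
class CandidatePrediction:
    """A scored (head, relation, disease-tail) hypothesis."""

    head: str
    relation: str
    tail: str
    score: float
    rank: int
    novel: bool


def enumerate_candidates(
    category: CandidateCategory,
    ad_tails: Iterable[str],
    entity_index: Mapping[str, int],
    relation_index: Mapping[str, int],
) -> list[tuple[str, str, str]]:
    """Cartesian product heads x relations x tails, in deterministic order.

    Heads/tails missing from the entity index and relations missing from the
    relation index are skipped with a log message; an empty product raises.
    """
    heads = sorted(h for h in category.head_ids if h in entity_index)
    tails = sorted(t for t in ad_tails if t in entity_index)
    rels = sorted(r for r in category.relations if r in relation_index)
    for name, full, kept in (("heads", category.head_ids, heads),
                             ("tails", set(ad_tails), tails),
                             ("relations", category.relations, rels)):
        missing = len(full) - len(kept)
        if missing:
            logger.info("enumerate_candidates: skipped %d unindexed %s", missing, name)
    out = [(h, r, t) for h in heads for r in rels for t in tails]
    if not out:
        raise ValueError("no candidate triples left after skipping unindexed concepts")
    return out


def score_and_rank(
    model: M.EmbeddingModel,
    candidates: Sequence[tuple[str, str, str]],
    entity_index: Mapping[str, int],
    relation_index: Mapping[str, int],
    training_triples: Iterable[tuple[str, str, str]] = (),
    novel_only: bool = True,
) -> list[CandidatePrediction]:
    """Score candidates and rank them descending, ties broken lexicographically.

    ``novel_only`` drops candidates already asserted in training (repurposing
    looks for new links); otherwise known triples are kept and flagged
    ``novel=False``.
    """
    import numpy as np

    known = set(training_triples)
    cand = list(candidates)
    if not cand:
        return []
    h = np.array([entity_index[c[0]] for c in cand])
    r = np.array([relation_index[c[1]] for c in cand])
    t = np.array([entity_index[c[2]] for c in cand])
    scores = M.score_batch(model, h, r, t)
    rows = [
        (c, float(s), c not in known)
        for c, s in zip(cand, scores)
        if not (novel_only and c in known)
    ]
    rows.sort(key=lambda x: (-x[1], x[0]))
    return [
        CandidatePrediction(head=c[0], relation=c[1], tail=c[2], score=s,
                            rank=i + 1, novel=nov)
        for i, (c, s, nov) in enumerate(rows)
    ]


def rank_per_group(
    predictions: Sequence[CandidatePrediction],
) -> dict[tuple[str, str], list[CandidatePrediction]]:
    """Re-rank predictions within each (relation, tail) group."""
    groups: dict[tuple[str, str], list[CandidatePrediction]] = {}
    for p in predictions:
        groups.setdefault((p.relation, p.tail), []).append(p)
    out = {}
    for key, preds in groups.items():
        preds = sorted(preds, key=lambda p: (-p.score, p.head))
        out[key] = [
            CandidatePrediction(p.head, p.relation, p.tail, p.score, i + 1, p.novel)
            for i, p in enumerate(preds)
        ]
    return out


def frequency_rank(
    grouped: Mapping[tuple[str, str], Sequence[CandidatePrediction]],
    top_n: int = 10,
) -> list[tuple[str, int]]:
    """Entities ordered by appearances among each group's top-N predictions.

    The count universe is the per-(relation, tail) top-N lists, so an
    entity's maximum attainable count equals the number of groups.  Ties are
    broken by entity id.
    """
    counts: Counter[str] = Counter()
    for key in sorted(grouped):
        for p in sorted(grouped[key], key=lambda p: p.rank)[:top_n]:
            counts[p.head] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def export_rankings(
    predictions: Sequence[CandidatePrediction],
    frequencies: Sequence[tuple[str, int]],
    triples_path: str,
    frequencies_path: str,
) -> None:
    """Write the triple ranking and the entity-frequency ranking as CSV."""
    if not predictions or not frequencies:
        raise ValueError("export_rankings requires non-empty inputs")
    with open(triples_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["head", "relation", "tail", "score", "rank", "novel"])
        for p in predictions:
            w.writerow([p.head, p.relation, p.tail, f"{p.score:.6f}", p.rank, int(p.novel)])
    with open(frequencies_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["entity", "appearances"])
        for ent, c in frequencies:
            w.writerow([ent, c])


def read_rankings(triples_path: str) -> list[CandidatePrediction]:
    out = []
    with open(triples_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(CandidatePrediction(
                head=row["head"], relation=row["relation"], tail=row["tail"],
                score=float(row["score"]), rank=int(row["rank"]),
                novel=bool(int(row["novel"])),
            ))
    return out
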