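"""Core data model: predications, deduplicated triples, knowledge graph, temporal splits.

A *predication* is one subject-predicate-object assertion extracted from a
single sentence of the biomedical literature, carrying its provenance (PMID,
publication year, sentence, UMLS semantic types).  Many predications assert
the same (subject, predicate, object) triple; the knowledge graph is built
over the deduplicated triple set, with each triple remembering the earliest
year it was asserted so that the corpus can be split on publication time.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Default column mapping for the SemMedDB PREDICATION-table dialect, with a
#: flattened YEAR column standing in for the sentence/citation join of the
#: real database.
SEMMEDDB_DIALECT: dict[str, str] = {
    "subject_id": "SUBJECT_CUI",
    "subject_name": "SUBJECT_NAME",
    "subject_semtype": "SUBJECT_SEMTYPE",
    "predicate": "PREDICATE",
    "object_id": "OBJECT_CUI",
    "object_name": "OBJECT_NAME",
    "object_semtype": "OBJECT_SEMTYPE",
    "pmid": "PMID",
    "year": "YEAR",
    "sentence": "SENTENCE",
}

_REQUIRED_FIELDS = ("subject_id", "predicate", "object_id")


@dataclass(frozen=True)
class Predication:
    """One subject-predicate-object assertion with provenance."""

    subject_id: str
    predicate: str
    object_id: str
    subject_name: str = ""
    subject_semtype: str = ""
    object_name: str = ""
    object_semtype: str = ""
    pmid: str = ""
    year: int | None = None
    sentence: str = ""

    def __post_init__(self) -> None:
        if not self.subject_id or not self.predicate or not self.object_id:
            raise ValueError(
                "subject_id, predicate and object_id must be non-empty, got "
                f"({self.subject_id!r}, {self.predicate!r}, {self.object_id!r})"
            )
        if self.year is not None and (not isinstance(self.year, int) or self.year <= 0):
            raise ValueError(f"year must be a positive integer or None, got {self.year!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.predicate, self.object_id)


@dataclass(frozen=True, order=True)
class Triple:
    """A deduplicated (head, relation, tail) assertion.

    ``first_year`` is the earliest publication year among the merged
    predications; ``None`` if no contributing predication carried a year.
    """

    head: str
    relation: str
    tail: str
    first_year: int | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.head, self.relation, self.tail)


@dataclass
class KnowledgeGraph:
    """Deduplicated triple store with dense entity/relation indices.

    ``adjacency`` maps (head index, tail index) -> number of distinct triples
    with that head-tail pair: the sparse adjacency matrix M whose row sums are
    out-degree centrality and column sums in-degree centrality.  A ``binary``
    flag clips every entry to 0/1 instead.
    """

    triples: list[Triple]
    entity_index: dict[str, int]
    relation_index: dict[str, int]
    adjacency: dict[tuple[int, int], int]
    binary_adjacency: bool = False

    @property
    def n_entities(self) -> int:
        return len(self.entity_index)

    @property
    def n_relations(self) -> int:
        return len(self.relation_index)

    @property
    def entities(self) -> list[str]:
        inv = sorted(self.entity_index, key=self.entity_index.__getitem__)
        return inv

    def triple_ids(self) -> list[tuple[int, int, int]]:
        """Triples as (head id, relation id, tail id) integer tuples."""
        e, r = self.entity_index, self.relation_index
        return [(e[t.head], r[t.relation], e[t.tail]) for t in self.triples]


@dataclass
class TemporalSplit:
    """Time-sliced partition of a triple set.

    Train holds triples first published before ``train_before``; validation
    holds first_year in [train_before, valid_through]; test holds first_year
    after ``valid_through``.  Triples without a year are excluded and counted.
    """

    train: list[Triple]
    validation: list[Triple]
    test: list[Triple]
    train_before: int
    valid_through: int
    n_excluded_missing_year: int = 0


def _parse_year(raw: str) -> int | None:
    raw = (raw or "").strip()
    if not raw:
        return None
    try:
        year = int(float(raw))
    except ValueError:
        return None
    return year if year > 0 else None


def read_predications(
    path: str,
    dialect: Mapping[str, str] = SEMMEDDB_DIALECT,
    delimiter: str = ",",
) -> list[Predication]:
    """Read predications from a delimited file with a header row.

    ``dialect`` maps Predication field names to column names.  Rows lacking a
    subject id, predicate or object id are skipped; the skip count is logged.
    An unparseable year leaves the field missing but keeps the row.
    """
    records: list[Predication] = []
    skipped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        for row in reader:
            # ids/codes are whitespace-stripped; names and sentences kept verbatim
            vals = {}
            for f, col in dialect.items():
                v = row.get(col) or ""
                vals[f] = v if f in ("subject_name", "object_name", "sentence") else v.strip()
            if any(not vals.get(f) for f in _REQUIRED_FIELDS):
                skipped += 1
                continue
            records.append(
                Predication(
                    subject_id=vals["subject_id"],
                    predicate=vals["predicate"],
                    object_id=vals["object_id"],
                    subject_name=vals.get("subject_name", ""),
                    subject_semtype=vals.get("subject_semtype", ""),
                    object_name=vals.get("object_name", ""),
                    object_semtype=vals.get("object_semtype", ""),
                    pmid=vals.get("pmid", ""),
                    year=_parse_year(vals.get("year", "")),
                    sentence=vals.get("sentence", ""),
                )
            )
    if skipped:
        logger.warning("read_predications: skipped %d rows missing required fields", skipped)
    return records


def write_predications(
    records: Sequence[Predication],
    path: str,
    dialect: Mapping[str, str] = SEMMEDDB_DIALECT,
    delimiter: str = ",",
) -> int:
    """Write predications as a delimited file readable by :func:`read_predications`."""
    fields = list(dialect)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([dialect[f] for f in fields])
        for rec in records:
            row = []
            for f in fields:
                v = getattr(rec, f)
                row.append("" if v is None else str(v))
            writer.writerow(row)
    return len(records)


def deduplicate(records: Iterable[Predication]) -> list[Triple]:
    """Collapse predications to distinct triples, keeping the earliest year.

    Missing years are ignored in the minimum; a triple whose every mention
    lacks a year gets ``first_year=None``.
    """
    first_year: dict[tuple[str, str, str], int | None] = {}
    order: list[tuple[str, str, str]] = []
    for rec in records:
        k = rec.key
        if k not in first_year:
            first_year[k] = rec.year
            order.append(k)
        elif rec.year is not None:
            cur = first_year[k]
            first_year[k] = rec.year if cur is None else min(cur, rec.year)
    return [Triple(h, r, t, first_year[(h, r, t)]) for h, r, t in order]


def build_graph(triples: Sequence[Triple], binary_adjacency: bool = False) -> KnowledgeGraph:
    """Index a deduplicated triple set and build the head-tail adjacency counts.

    Entities and relations get dense 0-based ids in lexicographic order so the
    graph is deterministic regardless of input order.  Duplicate (h, r, t)
    keys violate the dedup precondition and raise ``ValueError``.
    """
    keys = [t.key for t in triples]
    if len(set(keys)) != len(keys):
        dup = [k for k, c in Counter(keys).items() if c > 1][:3]
        raise ValueError(f"duplicate triples passed to build_graph, e.g. {dup}")
    entities = sorted({t.head for t in triples} | {t.tail for t in triples})
    relations = sorted({t.relation for t in triples})
    entity_index = {e: i for i, e in enumerate(entities)}
    relation_index = {r: i for i, r in enumerate(relations)}
    adjacency: dict[tuple[int, int], int] = Counter()
    for t in triples:
        adjacency[(entity_index[t.head], entity_index[t.tail])] += 1
    if binary_adjacency:
        adjacency = {k: 1 for k in adjacency}
    return KnowledgeGraph(list(triples), entity_index, relation_index, dict(adjacency), binary_adjacency)


def temporal_split(
    triples: Sequence[Triple], train_before: int, valid_through: int
) -> TemporalSplit:
    """Partition triples on first publication year.

    Train: first_year < train_before.  Validation: train_before <= first_year
    <= valid_through.  Test: first_year > valid_through.  Triples with missing
    first_year are excluded and counted.
    """
    if train_before > valid_through + 1:
        raise ValueError(
            f"train_before ({train_before}) must be <= valid_through + 1 ({valid_through + 1})"
        )
    train, valid, test = [], [], []
    excluded = 0
    for t in triples:
        if t.first_year is None:
            excluded += 1
        elif t.first_year < train_before:
            train.append(t)
        elif t.first_year <= valid_through:
            valid.append(t)
        else:
            test.append(t)
    if excluded:
        logger.info("temporal_split: excluded %d triples with missing year", excluded)
    return TemporalSplit(train, valid, test, train_before, valid_through, excluded)


def triples_to_tsv(triples: Sequence[Triple], path: str) -> int:
    """Serialize triples as 4-column TSV (head, relation, tail, first_year)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["head", "relation", "tail", "first_year"])
        for t in triples:
            writer.writerow([t.head, t.relation, t.tail, "" if t.first_year is None else t.first_year])
    return len(triples)


def triples_from_tsv(path: str) -> list[Triple]:
    out: list[Triple] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            y = row.get("first_year", "")
            out.append(Triple(row["head"], row["relation"], row["tail"], int(y) if y else None))
    return out
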