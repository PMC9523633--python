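"""Rule-based triple filtering.

Three stages prune the literature graph to a size embedding models can
handle: (1) a semantic-group blocklist drops predications whose subject or
object is a generic biomedical concept (Activities & Behaviors, Concepts &
Ideas, ...); (2) each triple is scored by the subject's out-degree
centrality, the object's in-degree centrality, and the G^2 log-likelihood-
ratio association between subject and object; (3) the three scores are
min-max normalized to [0, 1], summed into a composite, and the top-k triples
are kept -- with every triple touching the disease whitelist kept
unconditionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import KnowledgeGraph, Predication, Triple

logger = logging.getLogger(__name__)


@dataclass
class CentralityTable:
    """In/out degree centrality per entity id (column/row sums of M)."""

    a_in: np.ndarray
    a_out: np.ndarray
    entity_index: dict[str, int]

    def a_out_of(self, concept: str) -> float:
        return float(self.a_out[self.entity_index[concept]])

    def a_in_of(self, concept: str) -> float:
        return float(self.a_in[self.entity_index[concept]])


@dataclass
class ContingencyTable:
    """Observed counts with their independence expectations.

    ``expected[cell]`` is the product of the cell's per-axis marginal sums
    divided by N^(k-1), the usual expectation under full independence of the
    k classification axes.
    """

    observed: np.ndarray
    expected: np.ndarray
    total: float


@dataclass
class TripleScoreTable:
    """Per-triple raw and normalized filter scores.

    Columns of ``raw``: subject A_out, object A_in, pair G^2.  ``normalized``
    holds each column min-max scaled to [0, 1] (a constant column maps to all
    zeros); ``composite`` is the row sum, in [0, 3].
    """

    triples: list[Triple]
    raw: np.ndarray
    normalized: np.ndarray
    composite: np.ndarray


def semantic_type_filter(
    records: Sequence[Predication],
    blocklist: set[str],
    group_map: Mapping[str, str],
) -> tuple[list[Predication], int]:
    """Drop predications whose subject or object belongs to a blocked group.

    ``group_map`` maps semantic-type codes to semantic-group labels; semtypes
    it does not cover pass through (logged once).  Returns (retained,
    removed count).
    """
    unmapped: set[str] = set()
    retained: list[Predication] = []
    removed = 0
    for rec in records:
        groups = []
        for st in (rec.subject_semtype, rec.object_semtype):
            if st and st not in group_map:
                unmapped.add(st)
            groups.append(group_map.get(st))
        if any(g in blocklist for g in groups if g is not None):
            removed += 1
        else:
            retained.append(rec)
    if unmapped:
        logger.info("semantic_type_filter: %d unmapped semtypes passed through: %s",
                    len(unmapped), sorted(unmapped)[:10])
    return retained, removed


def degree_centrality(graph: KnowledgeGraph) -> CentralityTable:
    """Row/column sums of the graph's head-tail adjacency matrix M."""
    n = graph.n_entities
    a_in = np.zeros(n)
    a_out = np.zeros(n)
    for (h, t), c in graph.adjacency.items():
        a_out[h] += c
        a_in[t] += c
    return CentralityTable(a_in=a_in, a_out=a_out, entity_index=graph.entity_index)


def independence_expectation(observed: np.ndarray) -> ContingencyTable:
    """Expectation table under independence of every classification axis.

    For a k-dimensional count array with grand total N, the expected count in
    a cell is the product over axes of that cell's marginal sum, divided by
    N^(k-1).  Works for any rank >= 1.
    """
    observed = np.asarray(observed, dtype=float)
    if np.any(observed < 0):
        raise ValueError("observed counts must be non-negative")
    total = float(observed.sum())
    if total <= 0:
        raise ValueError("contingency table grand total must be positive")
    expected = np.ones_like(observed) * total
    for axis in range(observed.ndim):
        marginal = observed.sum(axis=tuple(a for a in range(observed.ndim) if a != axis))
        shape = [1] * observed.ndim
        shape[axis] = -1
        expected = expected * (marginal.reshape(shape) / total)
    return ContingencyTable(observed=observed, expected=expected, total=total)


def g_squared(table: ContingencyTable) -> float:
    """Log-likelihood-ratio statistic G^2 = 2 * sum O * log(O / E).

    Cells with O = 0 contribute 0 (the x*log x -> 0 limit); O > 0 where
    E = 0 is an error.
    """
    O, E = table.observed, table.expected
    pos = O > 0
    if np.any(pos & (E <= 0)):
        raise ValueError("observed > 0 where expected = 0: G^2 undefined")
    val = 2.0 * float(np.sum(O[pos] * np.log(O[pos] / E[pos])))
    return max(val, 0.0) if abs(val) < 1e-9 else val


def pair_association(
    records: Sequence[Predication],
    triple_level: bool = False,
) -> dict[tuple[str, str], float]:
    """G^2 association strength for every observed (subject, object) pair.

    For each pair the 2x2 mention-count table
    [[n(s,o), n(s,not o)], [n(not s,o), n(not s,not o)]] is built over all
    predication mentions (``triple_level=True`` counts each distinct triple
    once instead) and its G^2 returned.
    """
    if not records:
        raise ValueError("pair_association needs at least one record")
    if triple_level:
        keys = {rec.key for rec in records}
        pairs = [(s, o) for s, _, o in keys]
    else:
        pairs = [(rec.subject_id, rec.object_id) for rec in records]
    n = len(pairs)
    pair_counts: dict[tuple[str, str], int] = {}
    subj_counts: dict[str, int] = {}
    obj_counts: dict[str, int] = {}
    for s, o in pairs:
        pair_counts[(s, o)] = pair_counts.get((s, o), 0) + 1
        subj_counts[s] = subj_counts.get(s, 0) + 1
        obj_counts[o] = obj_counts.get(o, 0) + 1
    out: dict[tuple[str, str], float] = {}
    for (s, o), n_so in pair_counts.items():
        n_s, n_o = subj_counts[s], obj_counts[o]
        table = np.array(
            [[n_so, n_s - n_so], [n_o - n_so, n - n_s - n_o + n_so]], dtype=float
        )
        out[(s, o)] = g_squared(independence_expectation(table))
    return out


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi - lo <= 0:
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def composite_scores(
    triples: Sequence[Triple],
    centrality: CentralityTable,
    association: Mapping[tuple[str, str], float],
    total_degree: bool = False,
) -> TripleScoreTable:
    """Normalized composite filter score per triple.

    Components: subject out-degree, object in-degree, pair G^2 (with
    ``total_degree=True`` each endpoint contributes A_in + A_out instead).
    Each component is min-max normalized across the triples; the composite is
    their sum.  Missing centrality/association lookups raise ``KeyError``.
    """
    if not triples:
        raise ValueError("composite_scores needs at least one triple")
    raw = np.empty((len(triples), 3))
    idx = centrality.entity_index
    for i, t in enumerate(triples):
        hi, ti = idx[t.head], idx[t.tail]
        if total_degree:
            raw[i, 0] = centrality.a_out[hi] + centrality.a_in[hi]
            raw[i, 1] = centrality.a_out[ti] + centrality.a_in[ti]
        else:
            raw[i, 0] = centrality.a_out[hi]
            raw[i, 1] = centrality.a_in[ti]
        raw[i, 2] = association[(t.head, t.tail)]
    normalized = np.column_stack([_minmax(raw[:, j]) for j in range(3)])
    return TripleScoreTable(list(triples), raw, normalized, normalized.sum(axis=1))


def select_top_k(
    triples: Sequence[Triple],
    scores: TripleScoreTable,
    k: int,
    whitelist: set[str] | None = None,
    keep: str = "high",
) -> list[Triple]:
    """Keep whitelist-adjacent triples unconditionally plus the k best others.

    A triple whose head or tail is whitelisted is always retained.  Remaining
    slots (k minus the whitelist-retained count, floored at 0) are filled by
    composite score (descending for ``keep="high"``), ties broken by
    lexicographic (head, relation, tail).  The result preserves the rank
    order of selection.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if keep not in ("high", "low"):
        raise ValueError("keep must be 'high' or 'low'")
    whitelist = whitelist or set()
    wl = [t for t in triples if t.head in whitelist or t.tail in whitelist]
    rest = [
        (t, scores.composite[i])
        for i, t in enumerate(scores.triples)
        if t.head not in whitelist and t.tail not in whitelist
    ]
    sign = -1.0 if keep == "high" else 1.0
    rest.sort(key=lambda ts: (sign * ts[1], ts[0].key))
    slots = max(k - len(wl), 0)
    return wl + [t for t, _ in rest[:slots]]


def load_concept_list(path: str) -> set[str]:
    """Newline-delimited concept identifiers / group labels; # comments skipped."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split("\t")[0])
    return out


def load_group_map(path: str) -> dict[str, str]:
    """TSV of semtype<TAB>group rows; # comments skipped."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            semtype, group = line.split("\t", 1)
            out[semtype.strip()] = group.strip()
    return out


def scores_to_tsv(scores: TripleScoreTable, path: str) -> int:
    """Export per-triple filter scores as TSV."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["head", "relation", "tail", "a_out_s", "a_in_o", "g2",
                    "norm_a_out_s", "norm_a_in_o", "norm_g2", "composite"])
        for i, t in enumerate(scores.triples):
            w.writerow([t.head, t.relation, t.tail,
                        *(f"{x:.6g}" for x in scores.raw[i]),
                        *(f"{x:.6g}" for x in scores.normalized[i]),
                        f"{scores.composite[i]:.6g}"])
    return len(scores.triples)
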