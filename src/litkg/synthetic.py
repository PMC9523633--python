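"""Synthetic literature-style predication corpora with planted structure.

Entities get latent positions in R^m and each relation a latent translation
vector; a triple (h, r, t) is *rule-true* when x_h + v_r - x_t is short
(``structure="translational"``) or when a relation-weighted bilinear form
exceeds a threshold (``structure="bilinear"``) — the first regime is the
one a translational embedding model can provably fit, the second matches
the diagonal-bilinear families.  The generator emits the rule-true triples
as SemMedDB-style predications (1-3 mentions each, with PMIDs, publication
years straddling a time-slice boundary, semantic types, and label-correlated
sentences), withholds a held-out fraction plus all planted drug-to-disease
repurposing pairs, and adds uniformly random false predications as noise.

What this emulates: a co-mention knowledge graph whose links follow a
low-dimensional relational geometry, so that link prediction is learnable.
What it does not emulate: real MEDLINE vocabulary, citation growth curves,
or extraction-error correlations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Predication, Triple
from .relevance import LabeledTripleText, build_classifier_input

#: Semantic-type palette: code -> (group, is_blocked).  The blocked groups are
#: the generic ones a real pipeline prunes.
DEFAULT_SEMTYPES: dict[str, tuple[str, bool]] = {
    "phsu": ("Chemicals & Drugs", False),
    "orch": ("Chemicals & Drugs", False),
    "dsyn": ("Disorders", False),
    "gngm": ("Genes & Molecular Sequences", False),
    "ortf": ("Anatomy", False),
    "phsf": ("Physiology", False),
    "idcn": ("Concepts & Ideas", True),
    "acty": ("Activities & Behaviors", True),
    "inpr": ("Objects", True),
    "ocdi": ("Occupations", True),
    "orgt": ("Organizations", True),
    "phpr": ("Phenomena", True),
}

BLOCKED_GROUPS = {
    "Activities & Behaviors", "Concepts & Ideas", "Objects",
    "Occupations", "Organizations", "Phenomena",
}

RELATION_NAMES = ("TREATS", "PREVENTS", "AFFECTS", "INTERACTS_WITH")


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the desk-scale study conditions."""

    n_entities: int = 300
    n_relations: int = 4
    latent_dim: int = 8
    structure: str = "translational"  # or "bilinear"
    tau: float = 1.8                  # translational rule-truth radius
    tau_bilinear: float = 6.0
    relation_scale: float = 0.5
    fraction_blocked: float = 0.05
    n_category_decoys: int = 30
    n_ad_tails: int = 10
    heldout_fraction: float = 0.1
    noise_rate: float = 0.05
    year_lo: int = 2000
    train_before: int = 2019
    valid_through: int = 2020
    year_hi: int = 2024
    p_after_boundary: float = 0.25
    annotation_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities < 10:
            raise ValueError("n_entities must be >= 10")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.structure not in ("translational", "bilinear"):
            raise ValueError("structure must be 'translational' or 'bilinear'")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated corpus."""

    latent_entities: np.ndarray
    latent_relations: np.ndarray
    rule_true: set[tuple[str, str, str]]
    held_out: list[Triple]
    planted_pairs: list[Triple]
    noise_keys: set[tuple[str, str, str]]
    entity_ids: list[str]
    relation_names: list[str]
    semtype_of: dict[str, str]
    ad_tails: list[str]
    drug_heads: list[str]
    planted_heads_by_tail: dict[str, list[str]]
    group_map: dict[str, str] = field(default_factory=dict)


def _entity_id(i: int) -> str:
    return f"C{i:07d}"


def _relation_name(j: int) -> str:
    return RELATION_NAMES[j] if j < len(RELATION_NAMES) else f"RELATION_{j}"


def _true_sentence(sname: str, pred: str, oname: str) -> str:
    return (f"{sname} was reported to {pred.lower().replace('_', ' ')} {oname} "
            f"in a controlled clinical study .")


def _noise_sentence(sname: str, pred: str, oname: str) -> str:
    return (f"{sname} was mentioned alongside {oname} incidentally without "
            f"direct supporting evidence .")


def generate_kg(config: SyntheticConfig) -> tuple[list[Predication], SyntheticTruth]:
    """Generate a predication corpus plus its ground truth.

    Deterministic given ``config.seed``.  Raises if the rule-truth threshold
    yields no true triples.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_entities, config.n_relations
    X = rng.standard_normal((n, config.latent_dim))
    if config.structure == "translational":
        V = config.relation_scale * rng.standard_normal((m, config.latent_dim))
    else:
        V = rng.standard_normal((m, config.latent_dim))

    entity_ids = [_entity_id(i) for i in range(n)]
    relation_names = [_relation_name(j) for j in range(m)]

    # semantic types: a fraction of entities carry blocked generic types
    blocked_codes = [c for c, (_, b) in DEFAULT_SEMTYPES.items() if b]
    kept_codes = [c for c, (_, b) in DEFAULT_SEMTYPES.items() if not b]
    semtype_of: dict[str, str] = {}
    n_blocked = int(round(config.fraction_blocked * n))
    blocked_entities = set(rng.choice(n, size=n_blocked, replace=False).tolist())
    for i in range(n):
        pool = blocked_codes if i in blocked_entities else kept_codes
        semtype_of[entity_ids[i]] = pool[int(rng.integers(len(pool)))]

    # rule-true triples from the latent geometry
    true_ids: list[tuple[int, int, int]] = []
    for j in range(m):
        if config.structure == "translational":
            diff = (X + V[j])[:, None, :] - X[None, :, :]
            hit = np.linalg.norm(diff, axis=2) < config.tau
        else:
            hit = (X * V[j]) @ X.T > config.tau_bilinear
        np.fill_diagonal(hit, False)
        hs, ts = np.nonzero(hit)
        true_ids.extend((int(h), j, int(t)) for h, t in zip(hs, ts))
    if not true_ids:
        raise ValueError(
            "rule-truth threshold produced zero true triples; loosen tau "
            "(translational) or lower tau_bilinear (bilinear)"
        )
    rule_true = {
        (entity_ids[h], relation_names[j], entity_ids[t]) for h, j, t in true_ids
    }

    # disease-like tails: frequent non-blocked tail entities of relation 0
    treat_tails = Counter(t for h, j, t in true_ids if j == 0 and t not in blocked_entities)
    ad_tail_ids = [t for t, _ in treat_tails.most_common(config.n_ad_tails)]
    ad_tails = [entity_ids[t] for t in ad_tail_ids]

    # planted repurposing pairs: every rule-true (h, relation 0, ad-tail);
    # withheld from the emitted corpus entirely
    planted_set = {
        (h, j, t) for h, j, t in true_ids
        if j == 0 and t in set(ad_tail_ids) and h not in blocked_entities
    }
    planted_heads_by_tail: dict[str, list[str]] = {tail: [] for tail in ad_tails}
    for h, j, t in sorted(planted_set):
        planted_heads_by_tail[entity_ids[t]].append(entity_ids[h])
    planted_head_ids = sorted({h for h, _, _ in planted_set})
    decoy_pool = [
        i for i in range(n)
        if i not in blocked_entities and i not in set(planted_head_ids)
        and i not in set(ad_tail_ids)
    ]
    decoys = rng.choice(len(decoy_pool), size=min(config.n_category_decoys, len(decoy_pool)),
                        replace=False)
    drug_heads = sorted(
        [entity_ids[i] for i in planted_head_ids]
        + [entity_ids[decoy_pool[i]] for i in decoys]
    )

    # held-out fraction of the remaining rule-true triples
    remaining = sorted(set(true_ids) - planted_set)
    n_held = int(round(config.heldout_fraction * len(remaining)))
    held_idx = set(rng.choice(len(remaining), size=n_held, replace=False).tolist())
    held_out_ids = [remaining[i] for i in sorted(held_idx)]
    emitted_ids = [remaining[i] for i in range(len(remaining)) if i not in held_idx]

    # noise: uniformly random false triples
    n_noise = int(round(config.noise_rate * len(true_ids)))
    noise_ids: list[tuple[int, int, int]] = []
    true_set = set(true_ids)
    while len(noise_ids) < n_noise:
        h = int(rng.integers(n))
        t = int(rng.integers(n))
        j = int(rng.integers(m))
        if h != t and (h, j, t) not in true_set:
            noise_ids.append((h, j, t))

    def draw_first_year() -> int:
        if rng.random() < config.p_after_boundary:
            return int(rng.integers(config.valid_through + 1, config.year_hi + 1))
        return int(rng.integers(config.year_lo, config.valid_through + 1))

    predications: list[Predication] = []
    pmid = 0
    for (h, j, t), is_true in [(x, True) for x in emitted_ids] + [(x, False) for x in noise_ids]:
        sid, oid = entity_ids[h], entity_ids[t]
        sname, oname = f"Concept {h}", f"Concept {t}"
        pred = relation_names[j]
        first = draw_first_year()
        n_mentions = int(rng.integers(1, 4))
        years = [first] + [int(rng.integers(first, config.year_hi + 1))
                           for _ in range(n_mentions - 1)]
        make = _true_sentence if is_true else _noise_sentence
        for y in years:
            pmid += 1
            predications.append(Predication(
                subject_id=sid, predicate=pred, object_id=oid,
                subject_name=sname, object_name=oname,
                subject_semtype=semtype_of[sid], object_semtype=semtype_of[oid],
                pmid=f"PMID{pmid:07d}", year=y,
                sentence=make(sname, pred, oname),
            ))

    key = lambda ids: (entity_ids[ids[0]], relation_names[ids[1]], entity_ids[ids[2]])
    truth = SyntheticTruth(
        latent_entities=X,
        latent_relations=V,
        rule_true=rule_true,
        held_out=[Triple(*key(x)) for x in held_out_ids],
        planted_pairs=[Triple(*key(x)) for x in sorted(planted_set)],
        noise_keys={key(x) for x in noise_ids},
        entity_ids=entity_ids,
        relation_names=relation_names,
        semtype_of=semtype_of,
        ad_tails=ad_tails,
        drug_heads=drug_heads,
        planted_heads_by_tail=planted_heads_by_tail,
        group_map={c: g for c, (g, _) in DEFAULT_SEMTYPES.items()},
    )
    return predications, truth


def generate_annotations(
    predications: Sequence[Predication],
    truth: SyntheticTruth,
    annotation_noise: float = 0.1,
    seed: int = 0,
) -> list[LabeledTripleText]:
    """Noisy binary correctness labels over a predication corpus.

    The clean label is 1 when the predication's triple is rule-true and 0 for
    noise triples; each label flips independently with probability
    ``annotation_noise``.
    """
    if not 0 <= annotation_noise < 0.5:
        raise ValueError("annotation_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    out: list[LabeledTripleText] = []
    for rec in predications:
        label = 1 if rec.key in truth.rule_true else 0
        if rng.random() < annotation_noise:
            label = 1 - label
        out.append(LabeledTripleText(text=build_classifier_input(rec), label=label))
    return out


def corpus_summary(predications: Sequence[Predication]) -> dict:
    """Stage-count style report: mentions, triples, entities, relations, years."""
    triples = {p.key for p in predications}
    entities = {p.subject_id for p in predications} | {p.object_id for p in predications}
    years = Counter(p.year for p in predications if p.year is not None)
    return {
        "n_predications": len(predications),
        "n_triples": len(triples),
        "n_entities": len(entities),
        "n_relations": len({p.predicate for p in predications}),
        "per_year": dict(sorted(years.items())),
    }
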