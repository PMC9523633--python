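"""End-to-end orchestration of the filtering / training / ranking pipeline.

Stage order mirrors the literature-graph workflow: read predications,
drop generic-concept predications, keep the top-k composite-scored triples
(disease whitelist always kept), apply the relevance classifier, deduplicate,
split on publication time, train an embedding model on the past slice,
evaluate link prediction on the later slices, and rank repurposing
candidates.  Every filtering stage records input = retained + removed in the
run report, and one global seed fans out to per-stage derived seeds so each
stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

from . import evaluation, filtering, models, ranking, relevance
from .core import Predication, deduplicate, build_graph

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of "seed:stage", below 2^31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    """Everything run_pipeline needs; serializable for the run report."""

    output_dir: str = "results/pipeline"
    # filtering
    blocklist: set[str] = field(default_factory=lambda: set())
    group_map: dict[str, str] = field(default_factory=dict)
    whitelist: set[str] = field(default_factory=set)
    top_k: int = 10_000
    keep: str = "high"
    binary_adjacency: bool = False
    # relevance
    classifier_threshold: float = 0.5
    # temporal split
    train_before: int = 2019
    valid_through: int = 2020
    # training
    family: str = "TransE"
    train: models.TrainConfig = field(default_factory=models.TrainConfig)
    protocol: str = "filtered"
    # ranking
    categories: dict[str, list[str]] = field(default_factory=dict)
    category_relations: dict[str, list[str]] = field(default_factory=dict)
    top_n: int = 10
    novel_only: bool = True
    seed: int = 0

    def echo(self) -> dict:
        d = asdict(self)
        d["blocklist"] = sorted(self.blocklist)
        d["whitelist"] = sorted(self.whitelist)
        return d


def run_pipeline(
    records: Sequence[Predication],
    config: PipelineConfig,
    scorer: relevance.Scorer | None = None,
) -> dict:
    """Run all stages over in-memory predications; returns the run report.

    ``scorer`` is the relevance classifier (any text -> probability
    callable); when ``None`` the relevance stage is skipped and recorded as
    such.  Artifacts (report JSON, metrics CSV, rankings) are written under
    ``config.output_dir``.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    stages: list[dict] = []

    def record_stage(name: str, n_in: int, n_out: int) -> None:
        stages.append({"stage": name, "input": n_in, "retained": n_out,
                       "removed": n_in - n_out})
        logger.info("stage %-18s %8d -> %8d", name, n_in, n_out)

    record_stage("read", len(records), len(records))
    if not records:
        raise RuntimeError("pipeline aborted at read: no predications")

    # semantic-type blocklist
    retained, removed = filtering.semantic_type_filter(records, config.blocklist,
                                                       config.group_map)
    record_stage("semantic_filter", len(records), len(retained))
    records = retained

    # composite-score top-k triple filter, applied back to predications
    triples = deduplicate(records)
    if not triples:
        raise RuntimeError("pipeline aborted at score_filter: empty graph")
    graph = build_graph(triples, binary_adjacency=config.binary_adjacency)
    centrality = filtering.degree_centrality(graph)
    association = filtering.pair_association(records)
    scores = filtering.composite_scores(triples, centrality, association)
    kept_triples = filtering.select_top_k(triples, scores, config.top_k,
                                          config.whitelist, keep=config.keep)
    kept_keys = {t.key for t in kept_triples}
    n_in = len(records)
    records = [r for r in records if r.key in kept_keys]
    record_stage("score_filter", n_in, len(records))

    # relevance classifier
    if scorer is not None:
        records, removed = relevance.apply_relevance_filter(
            records, scorer, config.classifier_threshold)
        record_stage("relevance_filter", len(records) + removed, len(records))
    else:
        stages.append({"stage": "relevance_filter", "skipped": True})
    if not records:
        raise RuntimeError("pipeline aborted at relevance_filter: nothing retained")

    n_mentions = len(records)
    n_triples = len(deduplicate(records))
    record_stage("deduplicate", n_mentions, n_triples)

    # temporal split + training + link-prediction evaluation
    try:
        result = evaluation.time_slice_evaluate(
            records, config.train_before, config.valid_through,
            config.family,
            models.TrainConfig(**{**asdict(config.train),
                                  "seed": derive_seed(config.seed, "train")}),
            protocol=config.protocol,
        )
    except ValueError as exc:
        raise RuntimeError(f"pipeline aborted at training: {exc}") from exc

    evaluation.metrics_to_csv(result.test, os.path.join(config.output_dir, "test_metrics.csv"))
    models.save_checkpoint(result.model, os.path.join(config.output_dir, "model.npz"),
                           meta={"family": config.family, "seed": config.seed})

    # candidate ranking per category
    train_keys = [t.key for t in deduplicate(records)
                  if t.first_year is not None and t.first_year < config.train_before]
    rankings_report = {}
    for name, head_ids in sorted(config.categories.items()):
        rels = set(config.category_relations.get(name, ())) or None
        cat = ranking.CandidateCategory(name=name, head_ids=set(head_ids),
                                        relations=rels or set())
        try:
            cands = ranking.enumerate_candidates(cat, sorted(config.whitelist),
                                                 result.entity_index,
                                                 result.relation_index)
        except ValueError:
            logger.warning("category %s: no scoreable candidates; skipped", name)
            continue
        preds = ranking.score_and_rank(result.model, cands, result.entity_index,
                                       result.relation_index, train_keys,
                                       novel_only=config.novel_only)
        if not preds:
            continue
        grouped = ranking.rank_per_group(preds)
        freqs = ranking.frequency_rank(grouped, top_n=config.top_n)
        ranking.export_rankings(
            preds, freqs,
            os.path.join(config.output_dir, f"rankings_{name}.csv"),
            os.path.join(config.output_dir, f"frequencies_{name}.csv"),
        )
        rankings_report[name] = {
            "n_candidates": len(cands),
            "n_ranked": len(preds),
            "top_entities": freqs[: config.top_n],
        }

    report = {
        "stages": stages,
        "split": {"train": result.n_train, "validation": result.n_validation,
                  "test": result.n_test},
        "metrics": {
            "test": result.test.as_row(),
            "validation": result.validation.as_row() if result.validation else None,
        },
        "final_epoch_loss": result.loss_trace[-1],
        "rankings": rankings_report,
        "config": config.echo(),
    }
    for st in report["stages"]:
        if "removed" in st:
            assert st["input"] == st["retained"] + st["removed"]
    with open(os.path.join(config.output_dir, "run_report.json"), "w",
              encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
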