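"""Prune the predication corpus with the rule-based statistical filters.

Removes generic-concept predications by semantic group, scores every
distinct triple by subject out-degree, object in-degree and subject-object
G² association, and keeps the top-k composite-scored triples — always
retaining triples that touch the disease whitelist.
"""

import argparse
import json
import os

from litkg import core, filtering, synthetic

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", default="results/data")
parser.add_argument("--k", type=int, default=2000)
parser.add_argument("--out", default="results/filtering")
args = parser.parse_args()

records = core.read_predications(os.path.join(args.data, "predications.csv"))
truth = json.load(open(os.path.join(args.data, "truth.json")))

retained, removed = filtering.semantic_type_filter(
    records, set(synthetic.BLOCKED_GROUPS), truth["group_map"])
print(f"semantic filter: {len(records)} -> {len(retained)} predications "
      f"({removed} touched a blocked generic group)")

triples = core.deduplicate(retained)
graph = core.build_graph(triples)
scores = filtering.composite_scores(
    triples, filtering.degree_centrality(graph),
    filtering.pair_association(retained))
whitelist = set(truth["ad_tails"])
kept = filtering.select_top_k(triples, scores, args.k, whitelist)
n_wl = sum(1 for t in kept if t.head in whitelist or t.tail in whitelist)
print(f"composite filter: kept {len(kept)} of {len(triples)} triples "
      f"(top-{args.k} by score; {n_wl} disease-whitelist triples kept unconditionally)")

os.makedirs(args.out, exist_ok=True)
core.triples_to_tsv(kept, os.path.join(args.out, "kept_triples.tsv"))
filtering.scores_to_tsv(scores, os.path.join(args.out, "triple_scores.tsv"))
kept_keys = {t.key for t in kept}
core.write_predications([r for r in retained if r.key in kept_keys],
                        os.path.join(args.out, "predications_filtered.csv"))
print(f"wrote kept triples, per-triple scores and filtered predications under {args.out}/")
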