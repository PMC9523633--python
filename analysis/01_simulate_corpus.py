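"""Generate the synthetic literature corpus the downstream analyses consume.

Emits a SemMedDB-style predication table with planted translational
structure, publication years straddling the 2019/2020 time-slice boundary,
5% noise predications, and noisy correctness annotations.
"""

import argparse
import json
import os

from litkg import core, pipeline, synthetic

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", default="results/data")
args = parser.parse_args()

cfg = synthetic.SyntheticConfig(seed=args.seed)
preds, truth = synthetic.generate_kg(cfg)
annotations = synthetic.generate_annotations(
    preds, truth, cfg.annotation_noise,
    seed=pipeline.derive_seed(args.seed, "annotations"))

os.makedirs(args.out, exist_ok=True)
core.write_predications(preds, os.path.join(args.out, "predications.csv"))
with open(os.path.join(args.out, "annotations.tsv"), "w", encoding="utf-8") as fh:
    for a in annotations:
        fh.write(f"{a.text}\t{a.label}\n")
with open(os.path.join(args.out, "truth.json"), "w", encoding="utf-8") as fh:
    json.dump({
        "ad_tails": truth.ad_tails,
        "drug_heads": truth.drug_heads,
        "planted_heads_by_tail": truth.planted_heads_by_tail,
        "held_out": [t.key for t in truth.held_out],
        "group_map": truth.group_map,
    }, fh, indent=2)

summary = synthetic.corpus_summary(preds)
print(f"corpus: {summary['n_predications']} predications over "
      f"{summary['n_triples']} distinct triples, {summary['n_entities']} entities, "
      f"{summary['n_relations']} relations")
print(f"withheld: {len(truth.held_out)} held-out rule-true triples, "
      f"{len(truth.planted_pairs)} planted repurposing pairs")
print(f"wrote predications/annotations/truth under {args.out}/")
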