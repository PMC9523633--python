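"""Train the three embedding families under time-slicing and tabulate metrics.

Each model trains only on triples first published before 2019 and is scored
on triples first appearing after 2020 (filtered protocol, head+tail
queries): the standard check that the models predict genuinely new links.
Writes a per-family MR / MRR / Hits@k table.
"""

import argparse
import csv
import os

from litkg import core, evaluation, models, pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--relevant", default="results/relevance")
parser.add_argument("--dim", type=int, default=32)
parser.add_argument("--epochs", type=int, default=200)
parser.add_argument("--out", default="results/embedding")
args = parser.parse_args()

records = core.read_predications(os.path.join(args.relevant, "predications_relevant.csv"))
os.makedirs(args.out, exist_ok=True)

rows = []
for family in models.FAMILIES:
    cfg = models.TrainConfig(dim=args.dim, learning_rate=0.01, epochs=args.epochs,
                             batch_size=512,
                             seed=pipeline.derive_seed(args.seed, f"train-{family}"))
    res = evaluation.time_slice_evaluate(records, 2019, 2020, family, cfg)
    row = {"model": family, **{k: round(v, 4) for k, v in res.test.as_row().items()}}
    rows.append(row)
    models.save_checkpoint(res.model, os.path.join(args.out, f"{family.lower()}.npz"),
                           meta={"entities": sorted(res.entity_index,
                                                    key=res.entity_index.__getitem__),
                                 "relations": sorted(res.relation_index,
                                                     key=res.relation_index.__getitem__),
                                 "seed": args.seed})
    baseline = evaluation.random_hits_baseline(10, len(res.entity_index))
    print(f"{family:9s} test slice (n={res.test.n_queries} queries): "
          f"MR {row['MR']:.2f}  MRR {row['MRR']:.3f}  Hits@10 {row['Hits@10']:.3f} "
          f"(chance {baseline:.3f})")

with open(os.path.join(args.out, "link_prediction_metrics.csv"), "w",
          newline="", encoding="utf-8") as fh:
    w = csv.DictWriter(fh, fieldnames=list(rows[0]))
    w.writeheader()
    w.writerows(rows)
best = max(rows, key=lambda r: r["Hits@10"])
print(f"best family on this corpus: {best['model']}; "
      f"checkpoints and metrics table under {args.out}/")
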