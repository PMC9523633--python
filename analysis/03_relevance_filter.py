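"""Calibrate the relevance classifier and filter the predication stream.

Trains the bag-of-words baseline on the noisy annotations (a transformer
scored offline can be plugged in instead), reports held-out
precision/recall/F1, and drops predications scoring below the threshold.
"""

import argparse
import os

import numpy as np

from litkg import core, pipeline, relevance

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", default="results/data")
parser.add_argument("--filtered", default="results/filtering")
parser.add_argument("--threshold", type=float, default=0.5)
parser.add_argument("--out", default="results/relevance")
args = parser.parse_args()

data = []
with open(os.path.join(args.data, "annotations.tsv"), encoding="utf-8") as fh:
    for line in fh:
        line = line.rstrip("\n")
        if line:
            text, label = line.rsplit("\t", 1)
            data.append(relevance.LabeledTripleText(text, int(label)))

rng = np.random.default_rng(pipeline.derive_seed(args.seed, "classifier-split"))
order = rng.permutation(len(data))
cut = len(data) * 2 // 3
train = [data[i] for i in order[:cut]]
held = [data[i] for i in order[cut:]]
scorer = relevance.train_baseline_classifier(
    train, seed=pipeline.derive_seed(args.seed, "classifier"))
m = relevance.evaluate_classifier(
    [int(scorer(d.text) >= 0.5) for d in held], [d.label for d in held])
print(f"classifier held-out (n={len(held)}): precision {m.precision:.2f}, "
      f"recall {m.recall:.2f}, F1 {m.f1:.2f}")

records = core.read_predications(os.path.join(args.filtered, "predications_filtered.csv"))
retained, removed = relevance.apply_relevance_filter(records, scorer, args.threshold)
print(f"relevance filter at threshold {args.threshold}: "
      f"{len(records)} -> {len(retained)} predications ({removed} removed)")

os.makedirs(args.out, exist_ok=True)
core.write_predications(retained, os.path.join(args.out, "predications_relevant.csv"))
with open(os.path.join(args.out, "classifier_metrics.json"), "w", encoding="utf-8") as fh:
    import json

    json.dump({"precision": m.precision, "recall": m.recall, "f1": m.f1,
               "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn}, fh, indent=2)
print(f"wrote relevant predications and classifier metrics under {args.out}/")
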