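"""Rank repurposing candidates against the disease concepts.

Scores every (drug-category head, TREATS/PREVENTS, disease tail) triple with
the trained translational model, ranks triples per (relation, tail) list,
tallies entity appearances across the per-list top-10s, and checks that the
planted (withheld) drug-disease pairs outrank the decoys.
"""

import argparse
import json
import os

import numpy as np

from litkg import models, ranking

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", default="results/data")
parser.add_argument("--embedding", default="results/embedding")
parser.add_argument("--top-n", type=int, default=10)
parser.add_argument("--out", default="results/ranking")
args = parser.parse_args()

truth = json.load(open(os.path.join(args.data, "truth.json")))
ckpt = os.path.join(args.embedding, "transe.npz")
model = models.load_checkpoint(ckpt)
meta = json.load(open(ckpt + ".json"))
e = {ent: i for i, ent in enumerate(meta["entities"])}
r = {rel: i for i, rel in enumerate(meta["relations"])}

cat = ranking.CandidateCategory("drug", set(truth["drug_heads"]), {"TREATS"})
cands = ranking.enumerate_candidates(cat, truth["ad_tails"], e, r)
predictions = ranking.score_and_rank(model, cands, e, r, novel_only=False)
grouped = ranking.rank_per_group(predictions)
freqs = ranking.frequency_rank(grouped, top_n=args.top_n)

os.makedirs(args.out, exist_ok=True)
ranking.export_rankings(predictions, freqs,
                        os.path.join(args.out, "candidate_triples.csv"),
                        os.path.join(args.out, "entity_frequencies.csv"))

print(f"scored {len(cands)} candidate triples over {len(grouped)} "
      f"(relation, disease) lists")
print(f"top {min(5, len(freqs))} heads by appearances in per-list top-{args.top_n}:")
for ent, c in freqs[:5]:
    print(f"  {ent}  appears in {c} of {len(grouped)} lists")

planted_ranks, decoy_ranks = [], []
for (_, tail), preds_g in grouped.items():
    planted = set(truth["planted_heads_by_tail"].get(tail, ()))
    for p in preds_g:
        (planted_ranks if p.head in planted else decoy_ranks).append(p.rank)
print(f"planted withheld pairs: median rank {np.median(planted_ranks):.0f} "
      f"(n={len(planted_ranks)}) vs decoys {np.median(decoy_ranks):.0f} "
      f"(n={len(decoy_ranks)})")
print(f"wrote candidate and frequency tables under {args.out}/")
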