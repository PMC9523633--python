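# Methods

## Data model

A *predication* is one extracted assertion with provenance: subject/object
concept identifiers (CUI-like strings), names and semantic types, a
predicate label, PMID, publication year and source sentence.  Many
predications assert the same (head, relation, tail) *triple*; deduplication
keeps one triple per key and records `first_year`, the earliest year among
its mentions (mentions without a year are ignored; a triple dated by no
mention has a missing `first_year` and is excluded from temporal splits but
counted).  The *knowledge graph* indexes entities and relations with dense
0-based ids assigned in lexicographic order — so graph construction is
deterministic under input reordering, and indices are always rebuilt from
the surviving triples after any filtering stage — and stores the sparse
head–tail adjacency **M**, where M[h,t] counts distinct triples linking h to
t (a switch clips entries to 0/1 for a binary adjacency).

## Rule-based filtering

*Semantic blocklist.* A predication is removed iff its subject's or object's
semantic group is blocked.  The semtype→group map ships as a small editable
table covering the six blocked generic groups and common kept groups; the
full licensed semantic network is intentionally not bundled, and unmapped
semantic types pass through with a log message rather than being guessed.

*Composite score.* Each triple gets three raw components: the subject's
out-degree A_out, the object's in-degree A_in (row/column sums of M — the
directionally consistent choice for subject→object edges; a flag switches to
total degree per endpoint), and the subject–object G² computed from the 2×2
mention-count table [[n(s,o), n(s,¬o)], [n(¬s,o), n(¬s,¬o)]].  G² uses
*pre-deduplication* mention counts by default because association strength is
a statement about literature frequency, not graph topology (triple-level
counts are available behind a flag).  The independence expectation is the
general k-dimensional product-of-marginals form E = (∏ marginals)/N^(k−1),
so the contingency machinery also supports a three-way (subject, predicate,
object) table; the 2×2 pairwise table is the default.  Cells with O = 0
contribute 0 to G² (the x·log x → 0 limit); O > 0 with E = 0 is an error.

*Selection.* The three components are min–max normalized over the candidate
triples ([0,1] each; a constant component maps to all zeros) and summed into
a composite in [0,3].  `select_top_k` retains every triple whose head or
tail is whitelisted, then fills the remaining max(k − whitelisted, 0) slots
by composite score, descending by default — the blocklist has already
removed the generic hubs, so surviving high-centrality, high-association
triples are treated as signal; `keep="low"` inverts this.  Ties break
deterministically by (score, head, relation, tail).  The cutoff is a rank
cutoff k rather than a score threshold, which makes the retained size
predictable.

## Relevance calibration

Classifier input is the fixed template
`subject [SEP] predicate [SEP] object [SEP] sentence` (the final segment is
empty when no sentence is available).  The stage is scorer-agnostic: any
`text → [0,1]` callable is accepted, including a file-backed table of
probabilities produced by a transformer fine-tuned elsewhere.  The built-in
baseline is a CountVectorizer + logistic-regression pipeline — deterministic
given its seed, refusing single-class training data.  Filtering keeps
records with probability ≥ threshold (default 0.5, configurable; the stage
is applied per-predication, before deduplication).  Precision, recall and F1
are reported with explicit flags when a zero denominator makes a metric
undefined (reported as 0).

## Embedding models and training

Scoring functions over embeddings of dimension d:

* TransE: f = −‖h + r − t‖_p with p ∈ {1, 2} (default L2). f ≤ 0 always,
  with equality iff the translation is exact.
* DistMult: f = Σᵢ hᵢrᵢtᵢ, computed as `r·(h·t)` so head–tail symmetry holds
  *bitwise*, not just analytically.
* ComplEx: f = Re(Σᵢ hᵢrᵢt̄ᵢ) over complex coordinates stored as separate
  real/imaginary matrices; the term grouping makes the all-real case reduce
  exactly to DistMult and purely imaginary relations exactly antisymmetric.

Training minimizes Σ log(1 + exp(−y·f)) (softplus form, stable to |f| ≈ 1e3)
by plain mini-batch SGD — no momentum or weight decay, the simplest
optimizer consistent with a stated learning rate.  Negatives corrupt each
positive by a fair coin choice of head or tail, replacing it uniformly over
the other entities; accidental true triples are *not* filtered by default
(uniform corruption; a flag enables filtered sampling).  Initialization is
uniform(−6/√d, 6/√d), the classic translational-embedding recipe, and TransE
entity vectors are projected back to the unit L2 sphere after every update.
Analytic gradients are hand-derived per family; `gradient_check` verifies
them against central finite differences (step 1e-5) and stays below 1e-4
relative error.

Defaults: learning rate 0.01 and dimension 250 with L2 distance (the
reference configuration for a full-scale literature graph); epochs 200,
batch size 512, one negative per positive.  The bundled analyses and the
acceptance script use dimension 32 on the ~300-entity synthetic corpus —
capacity matched to the problem size so the full study runs in seconds —
with all other hyperparameters at their defaults.

## Link-prediction evaluation

For each test triple and side (head and tail both, averaged), every entity
is substituted and scored; rank = 1 + #strictly-higher + #ties/2.  The
mean-of-tie-block policy avoids order-of-enumeration bias: an all-tied list
of n candidates yields rank (n+1)/2.  The *filtered* protocol (default, the
field's standard) removes candidates that would form another known-true
triple before counting; filtered rank ≤ raw rank per query.  MR is the mean
rank, MRR the mean reciprocal rank (MRR ≥ 1/MR by Jensen), Hits@k the
fraction of queries with rank ≤ k; chance level for Hits@k is k/(n−1).

*Time slicing.* Triples with first_year ≤ 2018 train, 2019–2020 validate,
≥ 2021 test ("before 1/1/2019" is read as a strict year cutoff, and the
validation window is inclusive).  The graph is indexed over all slices so
later triples are scoreable, but only the training slice reaches the
optimizer; train/test disjointness is asserted, and evaluation drops queries
whose head or tail never occurs in training (their embeddings are untrained
noise and would only add unhelpful variance).

## Candidate ranking

Candidates are the Cartesian product of a category's heads, its relations
(drug/chemical: TREATS+PREVENTS; supplement: AFFECTS), and the disease
tails, skipping unindexed concepts.  `novel_only` (default true) removes
triples already asserted in training — repurposing seeks new links.  The
frequency ranking counts each head's appearances among the per-(relation,
tail) top-N lists (N = 10), so the maximum attainable count equals the
number of disease concepts; this makes the frequency table's structure
reproducible whatever the concept list.

## Synthetic corpus generator

Entities receive latent positions x ~ N(0, I_m) (m = 8 by default) and each
relation a translation vector v (scale 0.5); (h, r, t) is rule-true iff
‖x_h + v_r − x_t‖ < τ (τ = 1.8, chosen so that ~1% of ordered pairs qualify,
giving ≈2.5–3k true triples at 300 entities and 4 relations).  A
`structure="bilinear"` variant defines truth by Σᵢ x_hᵢ w_rᵢ x_tᵢ > τ_b
instead, giving the bilinear families a matched regime.  The emitted corpus
is: rule-true triples minus a 10% held-out sample minus all planted
drug→disease pairs, each duplicated across 1–3 mentions with synthetic
PMIDs; plus noise_rate·|true| uniformly random false triples (5%).  First
years are drawn with probability 0.25 after the 2020 boundary (so ≥ 20% of
triples land in the test era), uniformly within each era over 2000–2024;
mention years never precede the first year.  5% of entities carry blocked
generic semantic types; sentences are label-correlated (distinct wording for
true vs noise mentions) so annotation text is informative, with labels
flipped at the configured annotation-noise rate (10%).

Disease-like tails are the most frequent non-blocked TREATS tails; planted
repurposing pairs are every rule-true (head, TREATS, disease-tail) triple,
withheld from the corpus entirely, and the drug category is those planted
heads plus 30 random decoys.  Because the withheld pairs follow the same
latent rule as the training triples, a model that recovers the geometry
ranks them above decoys — the generator's recoverability is what passing
tests demonstrate.

What the generator does not emulate: real vocabulary and sentence realism,
citation growth over time, correlated extraction errors, or scale-free
degree distributions.  Passing tests therefore establish correctness of the
machinery and learnability under the planted model, not performance on the
real literature.

## Numerical and degenerate-input choices

* G² is clamped to 0 when |value| < 1e-9 (pure round-off at independence).
* Min–max normalization of a constant score column yields zeros, making a
  single-triple corpus score 0 rather than NaN.
* A zero-norm TransE difference vector gets a zero gradient (subgradient at
  the optimum) instead of a division by zero.
* Temporal splits require train_before ≤ valid_through + 1; degenerate
  splits (empty train or test) abort with a stage-named error.
* One global seed fans out to per-stage seeds via crc32("seed:stage"), so
  stages are independently reproducible and all derived seeds stay < 2^31.

## Known limitations

Counts from a full SemMedDB run (hundreds of millions of predications) and
metrics of cluster-scale trained models are out of reach of the bundled
synthetic study and depend on the external database version; this package
reproduces the *procedures* and validates them on recoverable synthetic
structure at desk scale.  The baseline relevance classifier is a linear
bag-of-words model — adequate for the synthetic sentences, far below a
fine-tuned transformer on real text, which is why the stage is pluggable.
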