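"""Triple-relevance calibration stage.

Literature-mined predications carry extraction errors, so a binary
classifier scores each one for correctness from the text of its subject,
object, predicate and source sentence, and a probability threshold decides
what enters the graph.  The production-grade scorer is a fine-tuned
biomedical transformer run elsewhere and plugged in as any callable
``text -> probability``; a bag-of-words logistic-regression baseline is
built in so the pipeline is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import Predication

SEP = " [SEP] "

Scorer = Callable[[str], float]


@dataclass(frozen=True)
class LabeledTripleText:
    """Classifier input text with a correctness label (1 = triple is real)."""

    text: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.text:
            raise ValueError("text must be non-empty")


@dataclass
class ClassifierMetrics:
    """Precision/recall/F1 with confusion counts.

    An undefined metric (zero denominator) is reported as 0.0 with the
    corresponding ``undefined_*`` flag set.
    """

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    undefined_precision: bool = False
    undefined_recall: bool = False
    undefined_f1: bool = False


def build_classifier_input(record: Predication) -> str:
    """Deterministic 4-segment template: subject, predicate, object, sentence."""
    if not record.subject_name or not record.object_name or not record.predicate:
        raise ValueError("subject/object names and predicate must be non-empty")
    return SEP.join([record.subject_name, record.predicate, record.object_name,
                     record.sentence or ""])


def train_baseline_classifier(
    data: Sequence[LabeledTripleText], seed: int = 0
) -> Scorer:
    """Bag-of-words logistic regression returning P(label = 1 | text).

    Deterministic given the seed.  Raises on single-class data (no decision
    boundary to fit).
    """
    from sklearn.feature_extraction.text import CountVectorizer
    from sklearn.linear_model import LogisticRegression

    labels = np.array([d.label for d in data])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training data must contain both labels")
    texts = [d.text for d in data]
    vec = CountVectorizer(token_pattern=r"[^\s]+", lowercase=True)
    X = vec.fit_transform(texts)
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(X, labels)

    def scorer(text: str) -> float:
        proba = clf.predict_proba(vec.transform([text]))[0]
        return float(proba[list(clf.classes_).index(1)])

    return scorer


def apply_relevance_filter(
    records: Sequence[Predication],
    scorer: Scorer,
    threshold: float = 0.5,
) -> tuple[list[Predication], int]:
    """Keep records the scorer rates at or above the threshold.

    Returns (retained, removed count); retained + removed = input.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    retained = [r for r in records if scorer(build_classifier_input(r)) >= threshold]
    return retained, len(records) - len(retained)


def evaluate_classifier(
    predicted: Sequence[int], true: Sequence[int]
) -> ClassifierMetrics:
    """Precision, recall and F1 from parallel binary label vectors."""
    if len(predicted) != len(true):
        raise ValueError("predicted and true label vectors must have equal length")
    p = np.asarray(predicted)
    y = np.asarray(true)
    tp = int(np.sum((p == 1) & (y == 1)))
    fp = int(np.sum((p == 1) & (y == 0)))
    fn = int(np.sum((p == 0) & (y == 1)))
    tn = int(np.sum((p == 0) & (y == 0)))
    und_p, und_r = tp + fp == 0, tp + fn == 0
    precision = 0.0 if und_p else tp / (tp + fp)
    recall = 0.0 if und_r else tp / (tp + fn)
    und_f = precision + recall == 0
    f1 = 0.0 if und_f else 2 * precision * recall / (precision + recall)
    return ClassifierMetrics(precision, recall, f1, tp, fp, fn, tn, und_p, und_r, und_f)


def scorer_from_file(path: str) -> Scorer:
    """Load an externally computed text -> probability table (TSV: text<TAB>prob).

    Lets a transformer scored offline drive the filter; unseen texts raise.
    """
    table: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            text, prob = line.rsplit("\t", 1)
            table[text] = float(prob)

    def scorer(text: str) -> float:
        if text not in table:
            raise KeyError(f"no external score for text: {text[:60]!r}...")
        return table[text]

    return scorer
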