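"""Knowledge-graph embedding models: TransE, DistMult, ComplEx.

Each entity and relation is embedded in R^d (C^d for ComplEx, stored as a
real and an imaginary matrix).  A scoring function f(h, r, t) rates how
plausible a triple is:

* TransE      f = -|| h + r - t ||_p        (translation; p = 1 or 2)
* DistMult    f = sum_i h_i r_i t_i          (diagonal bilinear; symmetric)
* ComplEx     f = Re( sum_i h_i r_i conj(t_i) )   (handles asymmetry)

Training minimizes the logistic loss sum log(1 + exp(-y f)) over observed
triples (y = +1) and uniformly corrupted negatives (y = -1) by mini-batch
SGD with analytic gradients.  After every TransE update the touched entity
vectors are projected back to the unit L2 sphere, following the original
translational-embedding recipe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FAMILIES = ("TransE", "DistMult", "ComplEx")


@dataclass
class TrainConfig:
    """Hyperparameters for SGD training.

    Defaults follow the reference setting for the literature graph: embedding
    size 250, learning rate 0.01, L2 distance for TransE.  Epochs, batch size
    and negatives-per-positive are desk-scale defaults.
    """

    dim: int = 250
    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 512
    negatives_per_positive: int = 1
    norm_order: int = 2
    seed: int = 0
    init_scale: float | None = None  # default 6/sqrt(dim), the TransE recipe
    filtered_negatives: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be >= 1")
        if self.norm_order not in (1, 2):
            raise ValueError("norm_order must be 1 or 2")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")


@dataclass
class EmbeddingModel:
    """Entity/relation parameter matrices for one model family.

    For ComplEx the ``*_im`` matrices hold the imaginary parts; for the real
    families they are ``None``.
    """

    family: str
    entity_re: np.ndarray
    relation_re: np.ndarray
    entity_im: np.ndarray | None = None
    relation_im: np.ndarray | None = None
    norm_order: int = 2

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family == "ComplEx" and (self.entity_im is None or self.relation_im is None):
            raise ValueError("ComplEx requires imaginary parts")

    @property
    def n_entities(self) -> int:
        return self.entity_re.shape[0]

    @property
    def n_relations(self) -> int:
        return self.relation_re.shape[0]

    @property
    def dim(self) -> int:
        return self.entity_re.shape[1]


def init_model(
    family: str, n_entities: int, n_relations: int, config: TrainConfig
) -> EmbeddingModel:
    """Seed-controlled uniform(-s, s) initialization, s = 6/sqrt(d) by default."""
    rng = np.random.default_rng(config.seed)
    s = config.init_scale if config.init_scale is not None else 6.0 / np.sqrt(config.dim)
    d = config.dim

    def u(shape):
        return rng.uniform(-s, s, size=shape)

    if family == "ComplEx":
        return EmbeddingModel(family, u((n_entities, d)), u((n_relations, d)),
                              u((n_entities, d)), u((n_relations, d)))
    model = EmbeddingModel(family, u((n_entities, d)), u((n_relations, d)),
                           norm_order=config.norm_order)
    if family == "TransE":
        _renormalize_rows(model.entity_re, np.arange(n_entities))
    return model


def _renormalize_rows(mat: np.ndarray, rows: np.ndarray) -> None:
    norms = np.linalg.norm(mat[rows], axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    mat[rows] /= norms


def score_batch(
    model: EmbeddingModel, h: np.ndarray, r: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Vectorized f(h, r, t) over parallel index arrays."""
    h = np.asarray(h, dtype=int)
    r = np.asarray(r, dtype=int)
    t = np.asarray(t, dtype=int)
    for ids, n in ((h, model.n_entities), (r, model.n_relations), (t, model.n_entities)):
        if ids.size and (ids.min() < 0 or ids.max() >= n):
            raise IndexError("entity/relation id out of range")
    H, R, T = model.entity_re[h], model.relation_re[r], model.entity_re[t]
    if model.family == "TransE":
        d = H + R - T
        if model.norm_order == 1:
            return -np.abs(d).sum(axis=-1)
        return -np.sqrt((d * d).sum(axis=-1))
    if model.family == "DistMult":
        # R * (H * T) keeps the score exactly symmetric in h and t
        return (R * (H * T)).sum(axis=-1)
    Hi, Ri, Ti = model.entity_im[h], model.relation_im[r], model.entity_im[t]
    # Re(h r conj(t)) expanded over real/imaginary parts; grouping keeps the
    # all-real case exactly equal to DistMult
    return (R * (H * T) + R * (Hi * Ti) + Ri * (H * Ti) - Ri * (Hi * T)).sum(axis=-1)


def score(model: EmbeddingModel, h: int, r: int, t: int) -> float:
    """f(h, r, t) for a single triple."""
    return float(score_batch(model, np.array([h]), np.array([r]), np.array([t]))[0])


def score_candidates(model: EmbeddingModel, r: int, fixed: int, side: str) -> np.ndarray:
    """Score every entity substituted into one side of (?, r, fixed)/(fixed, r, ?).

    ``side="head"`` varies the head with ``fixed`` as tail; ``side="tail"``
    varies the tail.  Returns an array of length n_entities.
    """
    n = model.n_entities
    ids = np.arange(n)
    if side == "head":
        return score_batch(model, ids, np.full(n, r), np.full(n, fixed))
    if side == "tail":
        return score_batch(model, np.full(n, fixed), np.full(n, r), ids)
    raise ValueError("side must be 'head' or 'tail'")


def negative_sample(
    positive: tuple[int, int, int],
    n_entities: int,
    k: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """k corruptions of one triple: fair coin head/tail, uniform replacement.

    The replacement entity is uniform over all entities excluding the one it
    replaces; the relation is never corrupted.
    """
    if n_entities < 2:
        raise ValueError("need at least 2 entities to corrupt")
    h, r, t = positive
    out = []
    for _ in range(k):
        corrupt_head = rng.random() < 0.5
        orig = h if corrupt_head else t
        repl = int(rng.integers(0, n_entities - 1))
        if repl >= orig:
            repl += 1
        out.append((repl, r, t) if corrupt_head else (h, r, repl))
    return out


def logistic_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """sum log(1 + exp(-y f)), evaluated as a numerically stable softplus."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    z = -labels * scores
    # softplus(z) = log(1 + e^z) = max(z, 0) + log1p(exp(-|z|))
    return float(np.sum(np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))))


def _loss_grad_wrt_score(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    # d/df log(1+exp(-y f)) = -y * sigmoid(-y f)
    z = -labels * scores
    sig = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    return -labels * sig


def _score_gradients(
    model: EmbeddingModel, h: np.ndarray, r: np.ndarray, t: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-example gradients of f with respect to the involved embedding rows."""
    H, R, T = model.entity_re[h], model.relation_re[r], model.entity_re[t]
    if model.family == "TransE":
        d = H + R - T
        if model.norm_order == 1:
            g = np.sign(d)
        else:
            norms = np.linalg.norm(d, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            g = d / norms
        return {"h": -g, "r": -g, "t": g}
    if model.family == "DistMult":
        return {"h": R * T, "r": H * T, "t": H * R}
    Hi, Ri, Ti = model.entity_im[h], model.relation_im[r], model.entity_im[t]
    return {
        "h": R * T + Ri * Ti,
        "hi": R * Ti - Ri * T,
        "r": H * T + Hi * Ti,
        "ri": H * Ti - Hi * T,
        "t": H * R - Hi * Ri,
        "ti": Hi * R + H * Ri,
    }


def _apply_batch_update(
    model: EmbeddingModel,
    h: np.ndarray, r: np.ndarray, t: np.ndarray,
    labels: np.ndarray, lr: float,
) -> float:
    """One SGD step on a batch; returns the batch loss (pre-update)."""
    f = score_batch(model, h, r, t)
    loss = logistic_loss(f, labels)
    dl = _loss_grad_wrt_score(f, labels)[:, None]
    g = _score_gradients(model, h, r, t)
    np.add.at(model.entity_re, h, -lr * dl * g["h"])
    np.add.at(model.relation_re, r, -lr * dl * g["r"])
    np.add.at(model.entity_re, t, -lr * dl * g["t"])
    if model.family == "ComplEx":
        np.add.at(model.entity_im, h, -lr * dl * g["hi"])
        np.add.at(model.relation_im, r, -lr * dl * g["ri"])
        np.add.at(model.entity_im, t, -lr * dl * g["ti"])
    if model.family == "TransE":
        _renormalize_rows(model.entity_re, np.unique(np.concatenate([h, t])))
    return loss


def _corrupt_batch(
    pos: np.ndarray, n_entities: int, k: int, rng: np.random.Generator,
    known: set[tuple[int, int, int]] | None,
) -> np.ndarray:
    """Vectorized uniform corruption with the same semantics as negative_sample."""
    rep = np.repeat(pos, k, axis=0)
    m = rep.shape[0]
    corrupt_head = rng.random(m) < 0.5
    orig = np.where(corrupt_head, rep[:, 0], rep[:, 2])
    repl = rng.integers(0, n_entities - 1, size=m)
    repl = repl + (repl >= orig)
    if known is not None:
        # filtered sampling: redraw accidental true triples a few times
        for _ in range(10):
            cand = rep.copy()
            cand[corrupt_head, 0] = repl[corrupt_head]
            cand[~corrupt_head, 2] = repl[~corrupt_head]
            bad = np.array([tuple(row) in known for row in cand])
            if not bad.any():
                break
            redraw = rng.integers(0, n_entities - 1, size=bad.sum())
            repl[bad] = redraw + (redraw >= orig[bad])
    neg = rep.copy()
    neg[corrupt_head, 0] = repl[corrupt_head]
    neg[~corrupt_head, 2] = repl[~corrupt_head]
    return neg


def train(
    triples: Sequence[tuple[int, int, int]],
    family: str,
    n_entities: int,
    n_relations: int,
    config: TrainConfig,
) -> tuple[EmbeddingModel, list[float]]:
    """Mini-batch SGD training; returns the model and a per-epoch mean-loss trace.

    Deterministic given ``config.seed``: initialization, shuffling and
    corruption all derive from one generator.
    """
    pos = np.asarray(list(triples), dtype=int)
    if pos.size == 0:
        raise ValueError("training requires at least one triple")
    if n_entities < 2:
        raise ValueError("training requires at least 2 entities")
    model = init_model(family, n_entities, n_relations, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    known = {tuple(row) for row in pos} if config.filtered_negatives else None
    k = config.negatives_per_positive
    trace: list[float] = []
    for _ in range(config.epochs):
        perm = rng.permutation(len(pos))
        epoch_loss = 0.0
        n_examples = 0
        for start in range(0, len(pos), config.batch_size):
            batch = pos[perm[start:start + config.batch_size]]
            neg = _corrupt_batch(batch, n_entities, k, rng, known)
            hh = np.concatenate([batch[:, 0], neg[:, 0]])
            rr = np.concatenate([batch[:, 1], neg[:, 1]])
            tt = np.concatenate([batch[:, 2], neg[:, 2]])
            labels = np.concatenate([np.ones(len(batch)), -np.ones(len(neg))])
            epoch_loss += _apply_batch_update(model, hh, rr, tt, labels,
                                             config.learning_rate)
            n_examples += len(labels)
        trace.append(epoch_loss / n_examples)
    return model, trace


def gradient_check(family: str, dim: int = 8, seed: int = 0) -> float:
    """Max relative error of analytic vs central-difference loss gradients.

    Builds a tiny random model and batch, differentiates the total logistic
    loss with respect to every parameter matrix, and compares against central
    finite differences with step 1e-5.
    """
    if dim > 8:
        raise ValueError("gradient_check is meant for dim <= 8")
    rng = np.random.default_rng(seed)
    n_e, n_r, m = 5, 3, 12
    cfg = TrainConfig(dim=dim, seed=seed)
    model = init_model(family, n_e, n_r, cfg)
    # move off the unit sphere so the TransE check is at a generic point
    model.entity_re += 0.1 * rng.standard_normal(model.entity_re.shape)
    h = rng.integers(0, n_e, m)
    r = rng.integers(0, n_r, m)
    t = rng.integers(0, n_e, m)
    labels = rng.choice([-1.0, 1.0], m)

    def total_loss() -> float:
        return logistic_loss(score_batch(model, h, r, t), labels)

    # analytic gradients accumulated into dense parameter-shaped arrays
    f = score_batch(model, h, r, t)
    dl = _loss_grad_wrt_score(f, labels)[:, None]
    g = _score_gradients(model, h, r, t)
    mats: list[tuple[np.ndarray, np.ndarray]] = []
    for mat, idx, key in (
        (model.entity_re, h, "h"), (model.relation_re, r, "r"), (model.entity_re, t, "t"),
    ):
        acc = np.zeros_like(mat)
        np.add.at(acc, idx, dl * g[key])
        mats.append((mat, acc))
    if family == "ComplEx":
        for mat, idx, key in (
            (model.entity_im, h, "hi"), (model.relation_im, r, "ri"), (model.entity_im, t, "ti"),
        ):
            acc = np.zeros_like(mat)
            np.add.at(acc, idx, dl * g[key])
            mats.append((mat, acc))
    # merge duplicate references (entity_re appears for both h and t)
    merged: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for mat, acc in mats:
        key = id(mat)
        if key in merged:
            merged[key] = (mat, merged[key][1] + acc)
        else:
            merged[key] = (mat, acc)

    step = 1e-5
    max_err = 0.0
    for mat, analytic in merged.values():
        it = np.nditer(mat, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = mat[ix]
            mat[ix] = orig + step
            lp = total_loss()
            mat[ix] = orig - step
            lm = total_loss()
            mat[ix] = orig
            numeric = (lp - lm) / (2 * step)
            denom = max(abs(analytic[ix]), abs(numeric), 1e-8)
            max_err = max(max_err, abs(analytic[ix] - numeric) / denom)
    return max_err


def save_checkpoint(model: EmbeddingModel, path: str, meta: dict | None = None) -> None:
    """Write parameter matrices (.npz) with a JSON sidecar describing them."""
    import json

    arrays = {"entity_re": model.entity_re, "relation_re": model.relation_re}
    if model.family == "ComplEx":
        arrays["entity_im"] = model.entity_im
        arrays["relation_im"] = model.relation_im
    np.savez(path, **arrays)
    sidecar = {
        "family": model.family,
        "dim": model.dim,
        "n_entities": model.n_entities,
        "n_relations": model.n_relations,
        "norm_order": model.norm_order,
    }
    if meta:
        sidecar.update(meta)
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def load_checkpoint(path: str) -> EmbeddingModel:
    import json

    with open(str(path) + ".json", encoding="utf-8") as fh:
        meta = json.load(fh)
    data = np.load(str(path) if str(path).endswith(".npz") else str(path))
    return EmbeddingModel(
        meta["family"], data["entity_re"], data["relation_re"],
        data["entity_im"] if "entity_im" in data else None,
        data["relation_im"] if "relation_im" in data else None,
        norm_order=meta.get("norm_order", 2),
    )
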