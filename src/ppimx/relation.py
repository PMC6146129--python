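"""Document-level relation classification of candidate gene-ID pairs.

Every pair of distinct candidate gene IDs in an article yields two
entity-blinded classification instances -- mentions of the first gene become
GENE_A, of the second GENE_B, of every other candidate GENE_N -- one per
order, and every candidate additionally yields a self-pair instance using
GENE_S (a protein may interact with itself). The classifier never sees the
gene names themselves, only their context.

The model is a multi-window convolutional text classifier: word embeddings,
parallel convolutions with window sizes 3/4/5 (200 filters each by default),
ReLU, max-over-time pooling, dropout, and a binary softmax. Four zero-vectors
are padded at the start and end of the text and between sentences so every
window position is well-defined. At prediction time the positive-class
probabilities of all ensemble members over both orders of a pair are
averaged; pairs scoring strictly above 0.5 are extracted, and if none does,
the single highest-scoring pair is extracted (every relevant article contains
at least one pair).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Document, GeneMention, canonical_pair, snap_to_tokens
from .nn import autodiff as ad
from .nn.layers import Dense, Embedding, glorot
from .nn.optim import RMSProp

__all__ = [
    "GENE_A", "GENE_B", "GENE_S", "GENE_N",
    "RcInstance", "RcModelConfig", "RcTrainConfig",
    "RcModel", "RcEnsemble",
    "generate_instances", "rc_forward",
    "train_rc", "train_rc_ensemble",
    "score_pair", "predict_pairs",
    "build_rc_vocab", "pair_scores",
]

GENE_A = "GENE_A"
GENE_B = "GENE_B"
GENE_S = "GENE_S"
GENE_N = "GENE_N"
PAD = "<pad>"
UNK = "<unk>"


@dataclass
class RcInstance:
    """One entity-blinded classification instance for an ordered pair (or a
    self-pair) of candidate gene IDs over a whole document."""

    pmid: str
    first_id: str
    second_id: str
    sentences: list[list[str]]
    label: bool | None = None

    @property
    def is_self(self) -> bool:
        return self.first_id == self.second_id

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.first_id, self.second_id)

    def tokens(self) -> list[str]:
        return [t for s in self.sentences for t in s]


@dataclass
class RcModelConfig:
    """Multi-window CNN hyperparameters; pooled feature length is
    ``len(window_sizes) * filters``."""

    window_sizes: tuple[int, ...] = (3, 4, 5)
    filters: int = 200
    word_emb_dim: int = 200
    dropout: float = 0.5
    pad_width: int = 4
    max_tokens: int = 1500

    @property
    def pooled_dim(self) -> int:
        return len(self.window_sizes) * self.filters


@dataclass
class RcTrainConfig:
    """RMSProp for 30 epochs, batch size 8, learning rate 0.001; per-member
    random 80/20 train/dev split (document-level), checkpoint per epoch
    keeping the best pair-level dev F1; 10-member ensemble."""

    epochs: int = 30
    learning_rate: float = 0.001
    batch_size: int = 8
    ensemble_size: int = 10
    train_fraction: float = 0.8
    rho: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Instance generation


def _blind_segments(
    document: Document, mentions: Sequence[GeneMention]
) -> list[list[tuple[str, str | None]]]:
    """Per-sentence items ("text", None) / (placeholder slot, gene_id): each
    mention's token run collapses to a single slot. Overlapping mention spans
    are resolved longest-first."""
    resolved: list[tuple[int, int, str]] = []  # token-range + id
    taken: set[int] = set()
    for m in sorted(mentions, key=lambda m: (-(m.end - m.start), m.start)):
        if m.gene_id is None:
            continue
        rng = snap_to_tokens(document, m)
        if rng is None:
            continue
        covered = set(range(rng[0], rng[1] + 1))
        if covered & taken:
            continue
        taken.update(covered)
        resolved.append((rng[0], rng[1], m.gene_id))
    owner: dict[int, tuple[int, str]] = {}
    for a, b, gid in resolved:
        for i in range(a, b + 1):
            owner[i] = (a, gid)

    out: list[list[tuple[str, str | None]]] = []
    flat = 0
    for sent in document.tokens:
        items: list[tuple[str, str | None]] = []
        for t in sent:
            i = flat
            flat += 1
            if i in owner:
                start, gid = owner[i]
                if i == start:
                    items.append(("", gid))  # one slot per mention run
                continue
            items.append((document.token_text(t), None))
        out.append(items)
    return out


def generate_instances(
    document: Document,
    normalized_mentions: Sequence[GeneMention],
    gold_pairs: set[tuple[str, str]] | None = None,
    max_tokens: int = 1500,
) -> list[RcInstance]:
    """All |G|^2 instances for a document: two ordered instances per distinct
    unordered pair plus one GENE_S self-pair instance per candidate; labels
    assigned from ``gold_pairs`` (order-insensitive) when given."""
    ids = sorted({m.gene_id for m in normalized_mentions if m.gene_id})
    if not ids:
        return []
    segments = _blind_segments(document, normalized_mentions)

    def build(first: str, second: str) -> RcInstance:
        sents: list[list[str]] = []
        for items in segments:
            toks: list[str] = []
            for text, gid in items:
                if gid is None:
                    toks.append(text)
                elif first == second and gid == first:
                    toks.append(GENE_S)
                elif gid == first:
                    toks.append(GENE_A)
                elif gid == second:
                    toks.append(GENE_B)
                else:
                    toks.append(GENE_N)
            if toks:
                sents.append(toks)
        sents = _truncate(sents, max_tokens)
        label = None
        if gold_pairs is not None:
            label = canonical_pair(first, second) in {
                canonical_pair(*p) for p in gold_pairs
            }
        return RcInstance(document.pmid, first, second, sents, label)

    instances: list[RcInstance] = []
    for a in ids:
        for b in ids:
            instances.append(build(a, b))
    return instances


def _truncate(sentences: list[list[str]], cap: int) -> list[list[str]]:
    """Drop tokens from the end past ``cap``, but never cut the first
    occurrence of a bound (GENE_*) token."""
    total = sum(len(s) for s in sentences)
    if total <= cap:
        return sentences
    flat_first: dict[str, int] = {}
    i = 0
    for s in sentences:
        for t in s:
            if t in (GENE_A, GENE_B, GENE_S) and t not in flat_first:
                flat_first[t] = i
            i += 1
    keep = max([cap] + [j + 1 for j in flat_first.values()])
    out: list[list[str]] = []
    i = 0
    for s in sentences:
        kept = [t for j, t in enumerate(s, start=i) if j < keep]
        i += len(s)
        if kept:
            out.append(kept)
    return out


# ---------------------------------------------------------------------------
# Model


def build_rc_vocab(instances: Iterable[RcInstance]) -> dict[str, int]:
    """Token vocabulary: frozen zero PAD row 0, UNK, placeholders, then the
    lowercased training tokens."""
    vocab = {PAD: 0, UNK: 1, GENE_A: 2, GENE_B: 3, GENE_S: 4, GENE_N: 5}
    for inst in instances:
        for tok in inst.tokens():
            key = tok if tok in (GENE_A, GENE_B, GENE_S, GENE_N) else tok.lower()
            vocab.setdefault(key, len(vocab))
    return vocab


class RcModel:
    def __init__(
        self,
        cfg: RcModelConfig,
        vocab: dict[str, int],
        seed: int = 0,
        word_vectors: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.cfg = cfg
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        self.emb = Embedding(rng, len(vocab), cfg.word_emb_dim, frozen_rows=(vocab[PAD],))
        if word_vectors:
            for w, i in vocab.items():
                v = word_vectors.get(w)
                if v is not None and len(v) == cfg.word_emb_dim and i != vocab[PAD]:
                    self.emb.table.data[i] = v
        self.conv_W: list[ad.Tensor] = []
        self.conv_b: list[ad.Tensor] = []
        for w in cfg.window_sizes:
            self.conv_W.append(ad.parameter(glorot(rng, w * cfg.word_emb_dim, cfg.filters)))
            self.conv_b.append(ad.parameter(np.zeros(cfg.filters)))
        self.out = Dense(rng, cfg.pooled_dim, 2)

    def params(self) -> list[ad.Tensor]:
        return self.emb.params() + self.conv_W + self.conv_b + self.out.params()

    def get_weights(self) -> dict[str, np.ndarray]:
        w = {"emb": self.emb.table.data.copy(),
             "out_W": self.out.W.data.copy(), "out_b": self.out.b.data.copy()}
        for i, (cw, cb) in enumerate(zip(self.conv_W, self.conv_b)):
            w[f"conv_W_{i}"] = cw.data.copy()
            w[f"conv_b_{i}"] = cb.data.copy()
        return w

    def set_weights(self, w: Mapping[str, np.ndarray]) -> None:
        self.emb.table.data = np.array(w["emb"], dtype=np.float64)
        self.out.W.data = np.array(w["out_W"], dtype=np.float64)
        self.out.b.data = np.array(w["out_b"], dtype=np.float64)
        for i in range(len(self.conv_W)):
            self.conv_W[i].data = np.array(w[f"conv_W_{i}"], dtype=np.float64)
            self.conv_b[i].data = np.array(w[f"conv_b_{i}"], dtype=np.float64)

    # -- encoding -----------------------------------------------------------

    def _indices(self, inst: RcInstance) -> list[int]:
        """Padded index sequence: 4 PADs at start, end and between sentences."""
        p = [self.vocab[PAD]] * self.cfg.pad_width
        idx: list[int] = list(p)
        for si, sent in enumerate(inst.sentences):
            if si > 0:
                idx.extend(p)
            for tok in sent:
                key = tok if tok in (GENE_A, GENE_B, GENE_S, GENE_N) else tok.lower()
                idx.append(self.vocab.get(key, self.vocab[UNK]))
        idx.extend(p)
        return idx

    def _logits(
        self,
        batch: Sequence[RcInstance],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> ad.Tensor:
        seqs = [self._indices(inst) for inst in batch]
        lens = [len(s) for s in seqs]
        L = max(lens)
        pad_id = self.vocab[PAD]
        idx = np.full((len(batch), L), pad_id, dtype=np.intp)
        for i, s in enumerate(seqs):
            idx[i, : len(s)] = s
        x = self.emb(idx)  # (B, L, d)
        pooled: list[ad.Tensor] = []
        for w, W, b in zip(self.cfg.window_sizes, self.conv_W, self.conv_b):
            win = ad.windows(x, w)  # (B, L-w+1, w*d)
            feat = ad.relu((win @ W) + b)  # (B, n, F)
            n = L - w + 1
            mask = np.full((len(batch), n, 1), -1e9)
            for i, ln in enumerate(lens):
                mask[i, : ln - w + 1, 0] = 0.0
            pooled.append(ad.amax(feat + ad.constant(mask), axis=1))
        z = ad.concat(pooled, axis=1)  # (B, pooled_dim)
        if train and self.cfg.dropout > 0:
            assert rng is not None
            z = ad.dropout(z, self.cfg.dropout, rng)
        return self.out(z)

    def predict_proba(self, instances: Sequence[RcInstance]) -> np.ndarray:
        """Positive-class probability per instance (dropout disabled)."""
        if not instances:
            return np.zeros(0)
        out = np.zeros(len(instances))
        # chunk to bound padded-batch size
        step = 64
        for i in range(0, len(instances), step):
            chunk = instances[i : i + step]
            logits = self._logits(chunk, train=False)
            out[i : i + len(chunk)] = ad.softmax(logits.data)[:, 1]
        return out

    def loss(self, batch: Sequence[RcInstance], rng: np.random.Generator) -> ad.Tensor:
        logits = self._logits(batch, train=True, rng=rng)
        labels = np.array([1 if inst.label else 0 for inst in batch], dtype=np.intp)
        losses = ad.softmax_cross_entropy(logits, labels)
        from .nn.autodiff import sum_

        return sum_(losses * ad.constant(np.full(len(batch), 1.0 / len(batch))))


def rc_forward(instance: RcInstance, model: RcModel) -> float:
    """Positive-class probability for one instance (inference path)."""
    return float(model.predict_proba([instance])[0])


# ---------------------------------------------------------------------------
# Pair scoring / prediction


def pair_scores(
    models: Sequence[RcModel], instances: Sequence[RcInstance]
) -> dict[tuple[str, str], float]:
    """Mean positive probability per unordered pair over all ensemble members
    and both instance orders (self-pairs have a single instance)."""
    if not instances:
        return {}
    probs = np.mean([m.predict_proba(instances) for m in models], axis=0)
    sums: dict[tuple[str, str], list[float]] = {}
    for inst, p in zip(instances, probs):
        sums.setdefault(inst.pair, []).append(float(p))
    return {pair: float(np.mean(ps)) for pair, ps in sums.items()}


def score_pair(
    ensemble: "RcEnsemble", instances: Sequence[RcInstance], pair: tuple[str, str]
) -> float:
    """Score one unordered pair from a document's instance list; symmetric in
    the pair's order by construction."""
    scores = pair_scores([m.model for m in ensemble.members], instances)
    key = canonical_pair(*pair)
    if key not in scores:
        raise KeyError(f"pair {pair} not in the document's candidate set")
    return scores[key]


def predict_pairs(
    ensemble: "RcEnsemble", instances: Sequence[RcInstance]
) -> set[tuple[str, str]]:
    """Pairs with mean probability strictly above 0.5; if none qualifies and
    candidates exist, the single best pair (ties: lexicographically smallest
    canonical pair)."""
    scores = pair_scores([m.model for m in ensemble.members], instances)
    if not scores:
        return set()
    positive = {pair for pair, p in scores.items() if p > 0.5}
    if positive:
        return positive
    best = min(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return {best[0]}


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainedRc:
    model: RcModel
    seed: int
    best_f1: float
    best_epoch: int
    history: list[tuple[int, float]] = field(default_factory=list)


def _pair_level_f1(models: Sequence[RcModel], dev: Sequence[RcInstance]) -> float:
    """Micro pair F1 over dev documents using inference semantics
    (threshold 0.5 with highest-scoring fallback)."""
    by_doc: dict[str, list[RcInstance]] = {}
    for inst in dev:
        by_doc.setdefault(inst.pmid, []).append(inst)
    tp = fp = fn = 0
    for pmid, insts in by_doc.items():
        scores = pair_scores(models, insts)
        positive = {pair for pair, p in scores.items() if p > 0.5}
        if not positive and scores:
            best = min(scores.items(), key=lambda kv: (-kv[1], kv[0]))
            positive = {best[0]}
        gold = {inst.pair for inst in insts if inst.label}
        tp += len(positive & gold)
        fp += len(positive - gold)
        fn += len(gold - positive)
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def train_rc(
    instances: Sequence[RcInstance],
    train_cfg: RcTrainConfig,
    model_cfg: RcModelConfig,
    seed: int,
    vocab: dict[str, int] | None = None,
    word_vectors: Mapping[str, np.ndarray] | None = None,
) -> TrainedRc:
    """Train one classifier on a random document-level 80/20 train/dev split,
    checkpointing per epoch and keeping the best pair-level dev F1."""
    if len(instances) < 2:
        raise ValueError("need at least 2 labeled instances")
    if any(inst.label is None for inst in instances):
        raise ValueError("all training instances must be labeled")
    rng = np.random.default_rng(seed)
    pmids = sorted({inst.pmid for inst in instances})
    perm = rng.permutation(len(pmids))
    n_train = max(1, int(round(train_cfg.train_fraction * len(pmids))))
    if n_train == len(pmids):
        n_train = len(pmids) - 1
    train_pmids = {pmids[i] for i in perm[:n_train]}
    train = [i for i in instances if i.pmid in train_pmids]
    dev = [i for i in instances if i.pmid not in train_pmids]
    labels = {bool(i.label) for i in train}
    if len(labels) < 2:
        raise ValueError("training split contains a single class")

    vocab = vocab if vocab is not None else build_rc_vocab(train)
    model = RcModel(model_cfg, vocab, seed, word_vectors)
    opt = RMSProp(model.params(), lr=train_cfg.learning_rate, rho=train_cfg.rho)

    best_f1 = -1.0
    best_epoch = 0
    best_weights = model.get_weights()
    history: list[tuple[int, float]] = []
    order = np.arange(len(train))
    for epoch in range(1, train_cfg.epochs + 1):
        rng.shuffle(order)
        for s in range(0, len(order), train_cfg.batch_size):
            batch = [train[i] for i in order[s : s + train_cfg.batch_size]]
            loss = model.loss(batch, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.emb.enforce_frozen()
        f1 = _pair_level_f1([model], dev)
        history.append((epoch, f1))
        if f1 > best_f1:
            best_f1 = f1
            best_epoch = epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return TrainedRc(model, seed, best_f1, best_epoch, history)


@dataclass
class RcEnsemble:
    members: list[TrainedRc]
    model_cfg: RcModelConfig
    vocab: dict[str, int]
    master_seed: int = 0

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "kind": "rc_ensemble",
            "model_cfg": asdict(self.model_cfg),
            "vocab": self.vocab,
            "master_seed": self.master_seed,
            "members": [
                {"seed": m.seed, "best_f1": m.best_f1, "best_epoch": m.best_epoch}
                for m in self.members
            ],
        }
        meta["model_cfg"]["window_sizes"] = list(self.model_cfg.window_sizes)
        with open(os.path.join(directory, "config.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh)
        for i, m in enumerate(self.members):
            np.savez(os.path.join(directory, f"member_{i}.npz"), **m.model.get_weights())

    @classmethod
    def load(cls, directory: str) -> "RcEnsemble":
        with open(os.path.join(directory, "config.json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        cfg_d = dict(meta["model_cfg"])
        cfg_d["window_sizes"] = tuple(cfg_d["window_sizes"])
        cfg = RcModelConfig(**cfg_d)
        vocab = {k: int(v) for k, v in meta["vocab"].items()}
        members = []
        for i, mm in enumerate(meta["members"]):
            model = RcModel(cfg, vocab, seed=mm["seed"])
            with np.load(os.path.join(directory, f"member_{i}.npz")) as z:
                model.set_weights({k: z[k] for k in z.files})
            members.append(TrainedRc(model, mm["seed"], mm["best_f1"], mm["best_epoch"]))
        return cls(members, cfg, vocab, meta.get("master_seed", 0))


def train_rc_ensemble(
    instances: Sequence[RcInstance],
    train_cfg: RcTrainConfig,
    model_cfg: RcModelConfig,
    master_seed: int = 0,
    word_vectors: Mapping[str, np.ndarray] | None = None,
) -> RcEnsemble:
    """Ensemble of classifiers with distinct seeds and independent random
    80/20 splits, sharing one vocabulary."""
    if train_cfg.ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    vocab = build_rc_vocab(instances)
    master = np.random.default_rng(master_seed)
    seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=train_cfg.ensemble_size)]
    members = [
        train_rc(instances, train_cfg, model_cfg, seed, vocab, word_vectors)
        for seed in seeds
    ]
    return RcEnsemble(members, model_cfg, vocab, master_seed)
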