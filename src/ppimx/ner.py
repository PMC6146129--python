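"""Gene-mention sequence tagger: a CNN-LSTM hybrid.

Each word is composed from its lowercased character sequence by a
convolutional layer (character embeddings concatenated with character-*type*
embeddings, window 3, ReLU, max-over-time pooling), concatenated with a word
embedding and a word-*type* embedding, and fed through a bidirectional LSTM.
A per-token softmax layer yields a categorical distribution over the IOB1
tags B-GENE / I-GENE / O; training minimizes the mean per-token categorical
cross-entropy of each sequence.

Case information is carried entirely by the type embeddings (characters are
lowercased before lookup). Models are trained with SGD under exponential
learning-rate decay, checkpointed on development-set span F1 with early
stopping, and combined into an ensemble whose members are trained on
independent random halves of the data; the ensemble prediction averages the
per-token class distributions before decoding.

A recall-oriented post-processing step scans the document for gene names
from a lexicon (longest match first) and adds them as extra mentions wherever
they do not overlap a tagged span; obviously wrong additions are expected to
be weeded out downstream by gene normalization.
"""

from __future__ import annotations

import json
import os
import unicodedata
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .augment import repair_iob
from .corpus import (
    Corpus,
    Document,
    GeneMention,
    LabeledSequence,
    Provenance,
    decode_iob,
    project_to_iob,
)
from .nn import autodiff as ad
from .nn.layers import Dense, Embedding, LSTMCell, glorot
from .nn.optim import SGD

__all__ = [
    "NerModelConfig",
    "NerTrainConfig",
    "NerModel",
    "NerEnsemble",
    "char_type",
    "word_type",
    "sequence_loss",
    "build_vocabs",
    "examples_from_corpus",
    "train_ner",
    "train_ner_ensemble",
    "tag_document",
    "lexicon_scan",
    "span_f1",
    "TAGS",
]

TAGS = ("B-GENE", "I-GENE", "O")
TAG_INDEX = {t: i for i, t in enumerate(TAGS)}

CHAR_TYPES = ("lowercase", "uppercase", "punctuation", "other")
WORD_TYPES = ("all_lower", "mixed", "cap_first", "all_upper", "other")

PAD_CHAR = "\x00"
UNK_CHAR = "\x01"
UNK_WORD = "<unk>"


@dataclass
class NerModelConfig:
    """Architecture hyperparameters. Defaults follow the full-scale system:
    32-dim character embeddings with 50 filters over character trigrams,
    200-dim word vectors, 200 hidden units per LSTM direction, 3 tags."""

    char_emb_dim: int = 32
    char_type_emb_dim: int = 8
    char_filters: int = 50
    char_window: int = 3
    word_emb_dim: int = 200
    word_type_emb_dim: int = 32
    lstm_hidden: int = 200
    n_tags: int = 3

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def char_row(self) -> int:
        return self.char_emb_dim + self.char_type_emb_dim

    @property
    def lstm_input(self) -> int:
        return self.char_filters + self.word_emb_dim + self.word_type_emb_dim


@dataclass
class NerTrainConfig:
    """Optimization settings: SGD with exponential decay applied at every
    checkpoint, mini-batches of 20 sentences, checkpointing on development
    span F1 every 100 iterations, early stopping after 10 flat checkpoints,
    and a 10-member ensemble each trained on a random 50% subset."""

    learning_rate: float = 0.5
    lr_decay: float = 0.95
    max_iterations: int = 10_000
    batch_size: int = 20
    checkpoint_every: int = 100
    early_stop_patience: int = 10
    ensemble_size: int = 10
    subset_fraction: float = 0.5
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if not (0.0 < self.subset_fraction <= 1.0):
            raise ValueError("subset_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# Character / word features


def char_type(c: str) -> str:
    """Classify one character as lowercase, uppercase, punctuation or other
    (digits and whitespace fall in 'other')."""
    if len(c) != 1:
        raise ValueError("char_type takes a single character")
    if c.islower():
        return "lowercase"
    if c.isupper():
        return "uppercase"
    cat = unicodedata.category(c)
    if cat.startswith("P") or cat.startswith("S"):
        return "punctuation"
    return "other"


def word_type(w: str) -> str:
    """Shape class of a token over its alphabetic characters; tokens with no
    letters are 'other'."""
    if not w:
        raise ValueError("empty token")
    letters = [c for c in w if c.isalpha()]
    if not letters:
        return "other"
    if all(c.islower() for c in letters):
        return "all_lower"
    if all(c.isupper() for c in letters):
        return "all_upper"
    if w[0].isalpha() and w[0].isupper() and all(c.islower() for c in letters[1:]):
        return "cap_first"
    return "mixed"


def ascii_fold(c: str) -> str:
    """Offset-preserving feature-level folding of a non-ASCII character to an
    ASCII equivalent where one exists (e.g. alpha with diacritics); characters
    with no single-character equivalent are kept as-is (they will map to the
    unknown-character row)."""
    if ord(c) < 128:
        return c
    folded = unicodedata.normalize("NFKD", c)
    stripped = "".join(ch for ch in folded if not unicodedata.combining(ch))
    if len(stripped) == 1 and ord(stripped) < 128:
        return stripped
    return c


def sequence_loss(probs: Sequence[np.ndarray], onehots: Sequence[np.ndarray]) -> float:
    """Mean per-word categorical cross-entropy of one sequence:
    l = -(1/n) sum_i sum_j y_ij log p_ij."""
    if len(probs) != len(onehots):
        raise ValueError("probs and onehots must have equal length")
    n = len(probs)
    total = 0.0
    for p, y in zip(probs, onehots):
        p = np.asarray(p, dtype=float)
        y = np.asarray(y, dtype=float)
        # terms with y_ij = 0 contribute nothing (0 * log 0 := 0)
        total += -float(np.sum(y * np.log(np.where(y > 0, p, 1.0))))
    return total / n


# ---------------------------------------------------------------------------
# Vocabularies and training examples


NerExample = tuple[list[str], list[str]]  # token strings, IOB1 labels


def build_vocabs(examples: Iterable[NerExample]) -> tuple[dict[str, int], dict[str, int]]:
    """Word vocabulary (lowercased tokens + UNK) and character vocabulary
    (printable ASCII + training characters + PAD/UNK)."""
    words: dict[str, int] = {UNK_WORD: 0}
    chars: dict[str, int] = {PAD_CHAR: 0, UNK_CHAR: 1}
    for ch in map(chr, range(32, 127)):
        chars.setdefault(ch.lower(), len(chars))
    for tokens, _ in examples:
        for tok in tokens:
            words.setdefault(tok.lower(), len(words))
            for c in tok.lower():
                chars.setdefault(ascii_fold(c), len(chars))
    return words, chars


def examples_from_corpus(
    corpus: Corpus, mentions: Mapping[str, Sequence[GeneMention]] | None = None
) -> list[NerExample]:
    """Sentence-level (tokens, labels) training examples from an annotated
    corpus; ``mentions`` overrides the corpus's own annotation (e.g. after
    augmentation)."""
    out: list[NerExample] = []
    for doc in corpus.documents:
        ms = (mentions or corpus.mentions).get(doc.pmid, [])
        for seq in project_to_iob(doc, ms):
            toks = [doc.token_text(t) for t in seq.tokens]
            if toks:
                out.append((toks, list(seq.labels)))
    return out


# ---------------------------------------------------------------------------
# Model


class NerModel:
    """One CNN-LSTM tagger; see the module docstring for the architecture."""

    def __init__(
        self,
        cfg: NerModelConfig,
        word_vocab: dict[str, int],
        char_vocab: dict[str, int],
        seed: int = 0,
        word_vectors: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.cfg = cfg
        self.word_vocab = word_vocab
        self.char_vocab = char_vocab
        rng = np.random.default_rng(seed)
        self.char_emb = Embedding(rng, len(char_vocab), cfg.char_emb_dim)
        self.ctype_emb = Embedding(rng, len(CHAR_TYPES), cfg.char_type_emb_dim)
        self.word_emb = Embedding(rng, len(word_vocab), cfg.word_emb_dim)
        self.wtype_emb = Embedding(rng, len(WORD_TYPES), cfg.word_type_emb_dim)
        if word_vectors:
            for w, i in word_vocab.items():
                v = word_vectors.get(w)
                if v is not None and len(v) == cfg.word_emb_dim:
                    self.word_emb.table.data[i] = v
        fan_in = cfg.char_window * self.cfg.char_row
        self.W_char = ad.parameter(glorot(rng, fan_in, cfg.char_filters))
        self.b_char = ad.parameter(np.zeros(cfg.char_filters))
        self.lstm_f = LSTMCell(rng, cfg.lstm_input, cfg.lstm_hidden)
        self.lstm_b = LSTMCell(rng, cfg.lstm_input, cfg.lstm_hidden)
        self.out = Dense(rng, 2 * cfg.lstm_hidden, cfg.n_tags)

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[ad.Tensor]:
        return (
            self.char_emb.params()
            + self.ctype_emb.params()
            + self.word_emb.params()
            + self.wtype_emb.params()
            + [self.W_char, self.b_char]
            + self.lstm_f.params()
            + self.lstm_b.params()
            + self.out.params()
        )

    _WEIGHT_NAMES = (
        "char_emb", "ctype_emb", "word_emb", "wtype_emb", "W_char", "b_char",
        "lstm_f_W", "lstm_f_U", "lstm_f_b", "lstm_b_W", "lstm_b_U", "lstm_b_b",
        "out_W", "out_b",
    )

    def get_weights(self) -> dict[str, np.ndarray]:
        ts = (
            self.char_emb.table, self.ctype_emb.table, self.word_emb.table,
            self.wtype_emb.table, self.W_char, self.b_char,
            self.lstm_f.W, self.lstm_f.U, self.lstm_f.b,
            self.lstm_b.W, self.lstm_b.U, self.lstm_b.b,
            self.out.W, self.out.b,
        )
        return {n: t.data.copy() for n, t in zip(self._WEIGHT_NAMES, ts)}

    def set_weights(self, weights: Mapping[str, np.ndarray]) -> None:
        ts = (
            self.char_emb.table, self.ctype_emb.table, self.word_emb.table,
            self.wtype_emb.table, self.W_char, self.b_char,
            self.lstm_f.W, self.lstm_f.U, self.lstm_f.b,
            self.lstm_b.W, self.lstm_b.U, self.lstm_b.b,
            self.out.W, self.out.b,
        )
        for n, t in zip(self._WEIGHT_NAMES, ts):
            t.data = np.array(weights[n], dtype=np.float64)

    # -- encoding -----------------------------------------------------------

    def _char_indices(self, word: str, width: int) -> tuple[list[int], list[int], int]:
        """Index sequences for one word padded to ``width``; returns char idx,
        char-type idx and the number of valid convolution windows."""
        chars = [ascii_fold(c) for c in word.lower()]
        true_len = max(len(chars), self.cfg.char_window)
        cidx = [self.char_vocab.get(c, self.char_vocab[UNK_CHAR]) for c in chars]
        tidx = [CHAR_TYPES.index(char_type(c)) for c in word[: len(chars)]]
        pad_to = max(width, true_len)
        while len(cidx) < pad_to:
            cidx.append(self.char_vocab[PAD_CHAR])
            tidx.append(CHAR_TYPES.index("other"))
        n_windows = true_len - self.cfg.char_window + 1
        return cidx, tidx, n_windows

    def _encode_chars(self, words: Sequence[str]) -> ad.Tensor:
        """Character-composed word vectors u for a flat word list: (N, kappa)."""
        w = self.cfg.char_window
        width = max([w] + [len(word) for word in words])
        cidx, tidx, valid = [], [], []
        for word in words:
            ci, ti, nw = self._char_indices(word, width)
            cidx.append(ci)
            tidx.append(ti)
            valid.append(nw)
        cidx_a = np.array(cidx, dtype=np.intp)
        tidx_a = np.array(tidx, dtype=np.intp)
        B = ad.concat([self.char_emb(cidx_a), self.ctype_emb(tidx_a)], axis=2)
        win = ad.windows(B, w)  # (N, width-w+1, w*row)
        feat = ad.relu((win @ self.W_char) + self.b_char)  # (N, nwin, kappa)
        nwin = feat.shape[1]
        mask = np.full((len(words), nwin, 1), -1e9)
        for i, nv in enumerate(valid):
            mask[i, :nv, 0] = 0.0
        return ad.amax(feat + ad.constant(mask), axis=1)  # (N, kappa)

    def encode_word_chars(self, word: str) -> np.ndarray:
        """Character-CNN composition u for a single word (inference)."""
        return self._encode_chars([word]).data[0]

    def _word_index(self, tok: str) -> int:
        return self.word_vocab.get(tok.lower(), self.word_vocab[UNK_WORD])

    def _forward(
        self, batch_tokens: Sequence[Sequence[str]]
    ) -> tuple[ad.Tensor, np.ndarray, ad.Tensor]:
        """Logits (B*L, m), token mask (B, L) and context vectors (B, L, 2H)
        for a padded batch."""
        Bn = len(batch_tokens)
        L = max(len(t) for t in batch_tokens)
        words: list[str] = []
        widx = np.zeros((Bn, L), dtype=np.intp)
        wtidx = np.zeros((Bn, L), dtype=np.intp)
        mask = np.zeros((Bn, L))
        for i, toks in enumerate(batch_tokens):
            for j in range(L):
                tok = toks[j] if j < len(toks) else ""
                words.append(tok)
                if tok:
                    widx[i, j] = self._word_index(tok)
                    wtidx[i, j] = WORD_TYPES.index(word_type(tok))
                    mask[i, j] = 1.0
        kappa = self.cfg.char_filters
        u = ad.reshape(self._encode_chars(words), (Bn, L, kappa))
        x = ad.concat([u, self.word_emb(widx), self.wtype_emb(wtidx)], axis=2)

        H = self.cfg.lstm_hidden
        zeros = ad.constant(np.zeros((Bn, H)))
        hf, cf = zeros, zeros
        hs_f: list[ad.Tensor] = []
        for t in range(L):
            hf, cf = self.lstm_f.step(ad.select_step(x, t), hf, cf, mask[:, t : t + 1])
            hs_f.append(hf)
        hb, cb = zeros, zeros
        hs_b: list[ad.Tensor] = [zeros] * L
        for t in reversed(range(L)):
            hb, cb = self.lstm_b.step(ad.select_step(x, t), hb, cb, mask[:, t : t + 1])
            hs_b[t] = hb
        h_all = ad.concat(
            [
                ad.reshape(ad.concat([hs_f[t], hs_b[t]], axis=1), (Bn, 1, 2 * H))
                for t in range(L)
            ],
            axis=1,
        )  # (B, L, 2H)
        logits = ad.reshape(h_all, (Bn * L, 2 * H)) @ self.out.W + self.out.b
        return logits, mask, h_all

    def encode_sequence(self, tokens: Sequence[str]) -> np.ndarray:
        """Bi-LSTM context vectors h_i (length 2*pi) for one sentence."""
        if not tokens:
            raise ValueError("empty token sequence")
        _, _, h_all = self._forward([list(tokens)])
        return h_all.data[0]

    def token_distribution(self, h: np.ndarray) -> np.ndarray:
        """Softmax categorical distribution from one context vector."""
        q = h @ self.out.W.data + self.out.b.data
        return ad.softmax(q)

    def predict_probs(self, tokens: Sequence[str]) -> np.ndarray:
        """(L, m) per-token tag distributions for one sentence."""
        if not tokens:
            return np.zeros((0, self.cfg.n_tags))
        logits, _, _ = self._forward([list(tokens)])
        return ad.softmax(logits.data)

    def predict_probs_batch(self, sents: Sequence[Sequence[str]]) -> list[np.ndarray]:
        if not sents:
            return []
        logits, mask, _ = self._forward(sents)
        L = mask.shape[1]
        probs = ad.softmax(logits.data).reshape(len(sents), L, self.cfg.n_tags)
        return [probs[i, : len(s)] for i, s in enumerate(sents)]

    def loss(
        self, batch: Sequence[NerExample], rng: np.random.Generator | None = None
    ) -> ad.Tensor:
        """Mean-over-examples of the per-sequence mean token cross-entropy."""
        tokens = [b[0] for b in batch]
        logits, mask, _ = self._forward(tokens)
        Bn, L = mask.shape
        labels = np.zeros(Bn * L, dtype=np.intp)
        weights = np.zeros(Bn * L)
        for i, (toks, labs) in enumerate(batch):
            for j, lab in enumerate(labs):
                labels[i * L + j] = TAG_INDEX[lab]
                weights[i * L + j] = 1.0 / (len(labs) * Bn)
        losses = ad.softmax_cross_entropy(logits, labels)
        from .nn.autodiff import sum_

        return sum_(losses * ad.constant(weights))


# ---------------------------------------------------------------------------
# Span scoring


def _spans(labels: Sequence[str]) -> set[tuple[int, int]]:
    spans: set[tuple[int, int]] = set()
    start = None
    fixed = repair_iob(labels)
    for i, lab in enumerate(fixed):
        if lab == "O":
            if start is not None:
                spans.add((start, i))
                start = None
        elif lab == "B-GENE":
            if start is not None:
                spans.add((start, i))
            start = i
        else:
            if start is None:
                start = i
    if start is not None:
        spans.add((start, len(fixed)))
    return spans


def span_f1(
    pred: Sequence[Sequence[str]], gold: Sequence[Sequence[str]]
) -> float:
    """Micro span-level F1 between predicted and gold label sequences."""
    tp = fp = fn = 0
    for p, g in zip(pred, gold):
        ps, gs = _spans(p), _spans(g)
        tp += len(ps & gs)
        fp += len(ps - gs)
        fn += len(gs - ps)
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def _dev_f1(model: NerModel, dev: Sequence[NerExample]) -> float:
    sents = [toks for toks, _ in dev]
    probs = model.predict_probs_batch(sents)
    pred = [[TAGS[k] for k in p.argmax(axis=1)] for p in probs]
    return span_f1(pred, [labs for _, labs in dev])


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainedNer:
    model: NerModel
    seed: int
    best_f1: float
    best_iteration: int
    history: list[tuple[int, float]] = field(default_factory=list)


def train_ner(
    examples: Sequence[NerExample],
    dev: Sequence[NerExample],
    train_cfg: NerTrainConfig,
    model_cfg: NerModelConfig,
    seed: int,
    word_vectors: Mapping[str, np.ndarray] | None = None,
    vocabs: tuple[dict[str, int], dict[str, int]] | None = None,
) -> TrainedNer:
    """Train one tagger; keep the checkpoint with the best dev span F1, stop
    early after ``early_stop_patience`` checkpoints without improvement.
    Fully reproducible for a fixed seed."""
    if not examples:
        raise ValueError("empty training set")
    if not dev:
        raise ValueError("empty development set")
    word_vocab, char_vocab = vocabs if vocabs else build_vocabs(examples)
    model = NerModel(model_cfg, word_vocab, char_vocab, seed, word_vectors)
    rng = np.random.default_rng(seed)
    opt = SGD(model.params(), train_cfg.learning_rate, train_cfg.lr_decay,
              train_cfg.clip_norm)

    best_f1 = -1.0
    best_iter = 0
    best_weights = model.get_weights()
    flat = 0
    history: list[tuple[int, float]] = []
    n = len(examples)
    it = 0
    while it < train_cfg.max_iterations:
        it += 1
        idx = rng.choice(n, size=min(train_cfg.batch_size, n), replace=False)
        batch = [examples[i] for i in idx]
        loss = model.loss(batch)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if it % train_cfg.checkpoint_every == 0:
            f1 = _dev_f1(model, dev)
            history.append((it, f1))
            if f1 > best_f1:
                best_f1 = f1
                best_iter = it
                best_weights = model.get_weights()
                flat = 0
            else:
                flat += 1
                if flat >= train_cfg.early_stop_patience:
                    break
            opt.decay_lr()
    model.set_weights(best_weights)
    return TrainedNer(model, seed, best_f1, best_iter, history)


@dataclass
class NerEnsemble:
    """Trained taggers sharing vocabularies and tag set; prediction averages
    the per-token class distributions across members before decoding."""

    members: list[TrainedNer]
    model_cfg: NerModelConfig
    word_vocab: dict[str, int]
    char_vocab: dict[str, int]
    master_seed: int = 0

    def predict_probs(self, tokens: Sequence[str]) -> np.ndarray:
        probs = [m.model.predict_probs(tokens) for m in self.members]
        return np.mean(probs, axis=0)

    def predict_labels(self, tokens: Sequence[str]) -> list[str]:
        probs = self.predict_probs(tokens)
        return repair_iob([TAGS[k] for k in probs.argmax(axis=1)])

    # -- persistence --------------------------------------------------------

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "kind": "ner_ensemble",
            "model_cfg": asdict(self.model_cfg),
            "word_vocab": self.word_vocab,
            "char_vocab": self.char_vocab,
            "tags": list(TAGS),
            "master_seed": self.master_seed,
            "members": [
                {"seed": m.seed, "best_f1": m.best_f1, "best_iteration": m.best_iteration}
                for m in self.members
            ],
        }
        with open(os.path.join(directory, "config.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh)
        for i, m in enumerate(self.members):
            np.savez(os.path.join(directory, f"member_{i}.npz"), **m.model.get_weights())

    @classmethod
    def load(cls, directory: str) -> "NerEnsemble":
        with open(os.path.join(directory, "config.json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        cfg = NerModelConfig(**meta["model_cfg"])
        word_vocab = {k: int(v) for k, v in meta["word_vocab"].items()}
        char_vocab = {k: int(v) for k, v in meta["char_vocab"].items()}
        members = []
        for i, mm in enumerate(meta["members"]):
            model = NerModel(cfg, word_vocab, char_vocab, seed=mm["seed"])
            with np.load(os.path.join(directory, f"member_{i}.npz")) as z:
                model.set_weights({k: z[k] for k in z.files})
            members.append(TrainedNer(model, mm["seed"], mm["best_f1"], mm["best_iteration"]))
        return cls(members, cfg, word_vocab, char_vocab, meta.get("master_seed", 0))


def train_ner_ensemble(
    examples: Sequence[NerExample],
    train_cfg: NerTrainConfig,
    model_cfg: NerModelConfig,
    master_seed: int = 0,
    word_vectors: Mapping[str, np.ndarray] | None = None,
) -> NerEnsemble:
    """Train an ensemble: each member gets a distinct seed and an independent
    random ``subset_fraction`` sample of the sentences; the complementary
    sentences are that member's development set."""
    if train_cfg.ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if len(examples) < 2:
        raise ValueError("need at least 2 training sequences")
    vocabs = build_vocabs(examples)
    master = np.random.default_rng(master_seed)
    seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=train_cfg.ensemble_size)]
    members: list[TrainedNer] = []
    n = len(examples)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        k = int(round(train_cfg.subset_fraction * n))
        idx = set(rng.choice(n, size=max(1, k), replace=False).tolist())
        train = [examples[i] for i in sorted(idx)]
        dev = [examples[i] for i in range(n) if i not in idx]
        if not dev:
            raise ValueError(
                "subset_fraction leaves no complementary development set; "
                "reserve a dev fraction"
            )
        members.append(
            train_ner(train, dev, train_cfg, model_cfg, seed, word_vectors, vocabs)
        )
    return NerEnsemble(members, model_cfg, vocabs[0], vocabs[1], master_seed)


# ---------------------------------------------------------------------------
# Document tagging and lexicon scan


def tag_document(ensemble: NerEnsemble, document: Document) -> list[GeneMention]:
    """Tag one segmented document: average member distributions per token,
    argmax, repair to valid IOB1 and decode to character spans."""
    mentions: list[GeneMention] = []
    for sent_tokens in document.tokens:
        toks = [document.token_text(t) for t in sent_tokens]
        if not toks:
            continue
        labels = ensemble.predict_labels(toks)
        seq = LabeledSequence(list(sent_tokens), labels)
        mentions.extend(decode_iob(seq, document, Provenance.MODEL))
    return mentions


def lexicon_scan(
    document: Document,
    lexicon: Mapping[str, Sequence[str]],
    existing: Sequence[GeneMention] = (),
) -> list[GeneMention]:
    """Add lexicon gene names found in the text as extra mentions.

    Matching is case-insensitive and anchored at token boundaries; candidate
    matches are ranked longest-first (ties: leftmost) and accepted greedily,
    skipping any that overlap an existing span or a previously accepted one.
    """
    text = document.full_text
    lower = text.lower()
    starts = {t[0] for t in document.all_tokens()}
    ends = {t[1] for t in document.all_tokens()}

    candidates: list[tuple[int, int]] = []
    for name in lexicon:
        if not name:
            continue
        key = name.lower()
        pos = lower.find(key)
        while pos != -1:
            end = pos + len(key)
            if pos in starts and end in ends:
                candidates.append((pos, end))
            pos = lower.find(key, pos + 1)

    candidates = sorted(set(candidates), key=lambda se: (-(se[1] - se[0]), se[0], se[1]))
    taken = [(m.start, m.end) for m in existing]
    added: list[GeneMention] = []
    for s, e in candidates:
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        added.append(GeneMention(s, e, text[s:e], Provenance.LEXICON))
    added.sort(key=lambda m: (m.start, m.end))
    return added
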