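"""Deterministic synthetic corpora and knowledge bundles for testing the
pipeline end to end without downloads.

The generator emits templated, natural-ish abstracts in which every article
carries at least one gold interaction pair: positive pairs co-occur with a
cue phrase ("interacts with", "promotes sumoylation of", "binds") and a
mutation phrase, negative gene co-occurrences carry no cue. Gene names mix
case/digit shapes ("Xbp7", "TRK9", "abc-1") so the character-type and
word-type features of the tagger have signal. Configurable fractions control
self-interactions, relations expressed across sentence boundaries, homolog
confusers (one name shared by two gene IDs in the same homology group -- the
Shank3-style human/rat ambiguity) and lexicon-only genes that appear only in
test-split articles (and in the lexicon), which the tagger cannot have
learned.

The accompanying knowledge bundle is oracle-consistent: every gold mention's
ID is reachable through the name index and the document indexes, so with the
undegraded bundle normalization recovers 100% of gold mention IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import (
    Corpus,
    Document,
    GeneMention,
    Provenance,
    canonical_pair,
    segment,
)
from .normalize import KnowledgeBundle

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "generate_fixture_bundle",
    "corrupt_knowledge",
    "measure_cross_sentence_fraction",
]


NOISE_WORDS = (
    "expression levels were measured in patient samples after treatment and "
    "the results showed significant changes relative to control while western "
    "blot analysis confirmed reduced protein abundance under stress conditions "
    "suggesting a regulatory role during early development of the disease"
).split()

MUTATION_WORDS = ("missense", "nonsense", "frameshift", "truncating", "germline")
TISSUES = ("hepatic", "neuronal", "cardiac", "epithelial", "renal")

#: ordinary-looking lowercase names for lexicon-only genes (the Sharpin
#: situation: nothing in the character shape marks them as genes, and they
#: never occur in NER training data)
PLAIN_GENE_NAMES = (
    "sharpin", "lumen", "cradle", "mantle", "tassel", "ember", "harbor",
    "willow", "quarry", "lattice", "meadow", "anchor",
)

#: cue-ambiguous sentences: the same lexical cues as the positive templates
#: but with ordinary nouns in the gene slots, all labeled O
AMBIGUOUS_SENTS = (
    "The adapter protein interacts with several partners in vitro .",
    "This variant binds chromatin near active promoters .",
    "The activated complex promotes sumoylation of substrate proteins .",
    "The truncated product forms homodimers under native conditions .",
)


@dataclass
class FixtureConfig:
    """Knobs of the generator; the seed fixes every random draw."""

    n_articles: int = 100
    n_genes: int = 40
    cross_sentence_frac: float = 0.25
    self_frac: float = 0.10
    confuser_rate: float = 0.10
    lexicon_only_rate: float = 0.15
    distractors_per_doc: int = 2
    word_vec_dim: int = 50
    train_frac: float = 0.6
    dev_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cross_sentence_frac", "self_frac", "confuser_rate",
                     "lexicon_only_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 2 and self.self_frac < 1.0:
            raise ValueError("need >= 2 genes unless every pair is a self-interaction")
        if self.train_frac + self.dev_frac >= 1.0:
            raise ValueError("train_frac + dev_frac must leave a test split")


@dataclass
class Gene:
    name: str
    gene_id: str
    group: str
    lexicon_only: bool = False


@dataclass
class FixtureBundle:
    train: Corpus
    dev: Corpus
    test: Corpus
    kb: KnowledgeBundle
    word_vectors: dict[str, np.ndarray]
    genes: list[Gene] = field(default_factory=list)

    def all_corpora(self) -> list[Corpus]:
        return [self.train, self.dev, self.test]


def _gene_name(rng: np.random.Generator, taken: set[str]) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    while True:
        style = rng.integers(0, 3)
        if style == 0:  # cap_first + digit: "Xbp7"
            name = (letters[rng.integers(0, 26)].upper()
                    + "".join(letters[i] for i in rng.integers(0, 26, size=2))
                    + str(rng.integers(1, 10)))
        elif style == 1:  # all upper + digit: "TRK9"
            name = ("".join(letters[i].upper() for i in rng.integers(0, 26, size=3))
                    + str(rng.integers(1, 10)))
        else:  # lower-hyphen: "abc-1"
            name = ("".join(letters[i] for i in rng.integers(0, 26, size=3))
                    + "-" + str(rng.integers(1, 10)))
        if name not in taken:
            taken.add(name)
            return name


def _make_inventory(cfg: FixtureConfig, rng: np.random.Generator) -> list[Gene]:
    genes: list[Gene] = []
    taken: set[str] = set()
    next_id = 10_000
    next_group = 1
    i = 0
    while i < cfg.n_genes:
        name = _gene_name(rng, taken)
        group = f"HG{next_group}"
        next_group += 1
        if rng.random() < cfg.confuser_rate and i + 1 < cfg.n_genes:
            # one name, two IDs, same homology group (species variants)
            genes.append(Gene(name, str(next_id), group))
            genes.append(Gene(name, str(next_id + 1), group))
            next_id += 2
            i += 2
        else:
            genes.append(Gene(name, str(next_id), group))
            next_id += 1
            i += 1
    n_lex = min(int(round(cfg.lexicon_only_rate * len(genes))), len(PLAIN_GENE_NAMES))
    picks = rng.permutation(len(PLAIN_GENE_NAMES))[:n_lex]
    for p in picks:
        genes.append(
            Gene(PLAIN_GENE_NAMES[p], str(next_id), f"HG{next_group}", lexicon_only=True)
        )
        next_id += 1
        next_group += 1
    return genes


def _noise(rng: np.random.Generator, n: int) -> list[str]:
    return [NOISE_WORDS[i] for i in rng.integers(0, len(NOISE_WORDS), size=n)]


@dataclass
class _Sent:
    tokens: list[str]
    genes: list[tuple[int, Gene]]  # token position -> gene


def _article_sentences(
    rng: np.random.Generator,
    doc_genes: list[Gene],
    positives: list[tuple[Gene, Gene]],
    cross: set[int],
) -> tuple[_Sent, list[_Sent]]:
    """Title sentence + abstract sentences realizing the configured pairs."""
    a0 = doc_genes[0]
    title = _Sent(
        ["Functional", "analysis", "of", a0.name, "variants", "in",
         str(TISSUES[rng.integers(0, len(TISSUES))]), "cells"],
        [(3, a0)],
    )
    sents: list[_Sent] = []
    for k, (ga, gb) in enumerate(positives):
        mut = MUTATION_WORDS[rng.integers(0, len(MUTATION_WORDS))]
        if ga.gene_id == gb.gene_id:
            toks = [ga.name, "forms", "homodimers", "and", "a", mut, "mutation",
                    "in", ga.name, "abolishes", "dimerization", "."]
            sents.append(_Sent(toks, [(0, ga), (8, ga)]))
        elif k in cross:
            s1 = _Sent(["We", "examined", "the", mut, "mutant", "form", "of",
                        ga.name, "."], [(7, ga)])
            s2 = _Sent(["This", "variant", "binds", gb.name, "and", "disrupts",
                        "its", "function", "."], [(3, gb)])
            sents.extend([s1, s2])
        else:
            style = rng.integers(0, 2)
            if style == 0:
                toks = [ga.name, "interacts", "with", gb.name, "and", "the", mut,
                        "mutation", "impairs", "this", "interaction", "."]
                sents.append(_Sent(toks, [(0, ga), (3, gb)]))
            else:
                toks = ["The", mut, "mutant", "of", ga.name, "promotes",
                        "sumoylation", "of", gb.name, "."]
                sents.append(_Sent(toks, [(4, ga), (8, gb)]))
    # negative fillers: remaining genes appear without a cue
    used = {g.gene_id for p in positives for g in p}
    for g in doc_genes:
        if g.gene_id not in used:
            toks = ["Levels", "of", g.name, "remained", "unchanged", "in",
                    "treated", "samples", "."]
            sents.append(_Sent(toks, [(2, g)]))
    filler = _noise(rng, 6)
    sents.append(_Sent([filler[0].capitalize()] + filler[1:] + ["."], []))
    amb = AMBIGUOUS_SENTS[rng.integers(0, len(AMBIGUOUS_SENTS))]
    sents.append(_Sent(amb.split(), []))
    order = rng.permutation(len(sents))
    return title, [sents[i] for i in order]


def _assemble(pmid: str, title: _Sent, sents: list[_Sent]) -> tuple[Document, list[GeneMention]]:
    mentions: list[GeneMention] = []

    def lay_out(sent: _Sent, offset: int) -> tuple[str, int]:
        text_parts: list[str] = []
        pos = offset
        for i, tok in enumerate(sent.tokens):
            for p, g in sent.genes:
                if p == i:
                    mentions.append(
                        GeneMention(pos, pos + len(tok), tok, Provenance.GOLD, g.gene_id)
                    )
            text_parts.append(tok)
            pos += len(tok) + 1
        return " ".join(text_parts), pos - 1

    title_text, end = lay_out(title, 0)
    abstract_parts: list[str] = []
    pos = end + 1
    for s in sents:
        text, end = lay_out(s, pos)
        abstract_parts.append(text)
        pos = end + 1
    doc = Document(pmid=pmid, title=title_text, abstract=" ".join(abstract_parts))
    segment(doc)
    for m in mentions:
        m.validate(doc)
    return doc, mentions


def generate_fixture_bundle(cfg: FixtureConfig) -> FixtureBundle:
    """Generate corpora (train/dev/test), an oracle-consistent knowledge
    bundle, a lexicon, a homolog map and random word vectors. Regeneration
    under the same seed is byte-identical."""
    rng = np.random.default_rng(cfg.seed)
    genes = _make_inventory(cfg, rng)
    main_genes = [g for g in genes if not g.lexicon_only]
    lex_genes = [g for g in genes if g.lexicon_only]
    if not main_genes:
        raise ValueError("inventory has no trainable genes")

    n_test = cfg.n_articles - int(round(cfg.train_frac * cfg.n_articles)) - int(
        round(cfg.dev_frac * cfg.n_articles)
    )
    n_train = int(round(cfg.train_frac * cfg.n_articles))
    splits = (["train"] * n_train
              + ["dev"] * (cfg.n_articles - n_train - n_test)
              + ["test"] * n_test)

    corpora = {"train": Corpus(), "dev": Corpus(), "test": Corpus()}
    kb = KnowledgeBundle()
    by_name: dict[str, list[str]] = {}
    for g in genes:
        by_name.setdefault(g.name, []).append(g.gene_id)
        kb.homolog_map[g.gene_id] = g.group
    kb.name_index = {name: list(ids) for name, ids in by_name.items()}
    kb.lexicon = {name: list(ids) for name, ids in by_name.items()}

    vocab: set[str] = set(w.lower() for w in NOISE_WORDS)
    for pmid_num, split in enumerate(splits, start=1):
        pmid = str(pmid_num)
        pool = list(main_genes)
        # choose document genes with pairwise-distinct names
        k = int(rng.integers(2, 5)) if cfg.self_frac < 1.0 else 1
        chosen: list[Gene] = []
        names: set[str] = set()
        order = rng.permutation(len(pool))
        want_lex = bool(
            split == "test" and lex_genes and rng.random() < cfg.lexicon_only_rate * 3
        )
        for i in order:
            g = pool[i]
            if g.name in names:
                continue
            chosen.append(g)
            names.add(g.name)
            if len(chosen) >= k:
                break
        if want_lex and len(chosen) >= 2:
            # lexicon-only gene as the second pair participant (never in the
            # title, so the tagger gets no title cue for it)
            gl = lex_genes[int(rng.integers(0, len(lex_genes)))]
            if gl.name not in names:
                chosen[1] = gl
        if not chosen:
            raise ValueError("could not select document genes")

        if rng.random() < cfg.self_frac or len(chosen) == 1:
            positives = [(chosen[0], chosen[0])]
        else:
            positives = [(chosen[0], chosen[1])]
            if len(chosen) >= 3 and rng.random() < 0.25:
                positives.append((chosen[0], chosen[2]))
        cross: set[int] = set()
        for idx, (ga, gb) in enumerate(positives):
            if ga.gene_id != gb.gene_id and rng.random() < cfg.cross_sentence_frac:
                cross.add(idx)

        title, sents = _article_sentences(rng, chosen, positives, cross)
        doc, mentions = _assemble(pmid, title, sents)
        corpus = corpora[split]
        corpus.documents.append(doc)
        corpus.mentions[doc.pmid] = sorted(mentions, key=lambda m: (m.start, m.end))
        corpus.pairs[doc.pmid] = {
            canonical_pair(a.gene_id, b.gene_id) for a, b in positives
        }

        doc_ids = {g.gene_id for g in chosen}
        distractors: set[str] = set()
        doc_names = {g.name for g in chosen}
        candidates = [g for g in genes if g.name not in doc_names]
        if candidates and cfg.distractors_per_doc:
            picks = rng.permutation(len(candidates))[: cfg.distractors_per_doc]
            distractors = {candidates[i].gene_id for i in picks}
        kb.doc_primary[pmid] = doc_ids | distractors
        kb.doc_fallback[pmid] = set(kb.doc_primary[pmid])

        for s in [title] + sents:
            vocab.update(t.lower() for t in s.tokens)

    word_vectors = {
        w: rng.uniform(-0.05, 0.05, size=cfg.word_vec_dim) for w in sorted(vocab)
    }
    return FixtureBundle(
        corpora["train"], corpora["dev"], corpora["test"], kb, word_vectors, genes
    )


def corrupt_knowledge(
    kb: KnowledgeBundle, drop_rate: float, seed: int = 0
) -> KnowledgeBundle:
    """Remove each (pmid, gene) entry of the primary document index
    independently with probability ``drop_rate``; the fallback index is left
    intact, so normalization flows through the fallback path."""
    if not (0.0 <= drop_rate <= 1.0):
        raise ValueError("drop_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    primary: dict[str, set[str]] = {}
    for pmid in sorted(kb.doc_primary):
        kept = {g for g in sorted(kb.doc_primary[pmid]) if rng.random() >= drop_rate}
        primary[pmid] = kept
    return KnowledgeBundle(
        name_index={k: list(v) for k, v in kb.name_index.items()},
        doc_primary=primary,
        doc_fallback={k: set(v) for k, v in kb.doc_fallback.items()},
        lexicon={k: list(v) for k, v in kb.lexicon.items()},
        homolog_map=dict(kb.homolog_map),
        mode=kb.mode,
    )


def measure_cross_sentence_fraction(corpus: Corpus) -> float:
    """Fraction of non-self gold pairs whose two genes never co-occur in one
    sentence of their article."""
    total = 0
    cross = 0
    for doc in corpus.documents:
        id_by_sent: list[set[str]] = []
        for sent_toks in doc.tokens:
            s0, e0 = sent_toks[0][0], sent_toks[-1][1]
            ids = {
                m.gene_id
                for m in corpus.mentions.get(doc.pmid, [])
                if m.gene_id and m.start >= s0 and m.end <= e0
            }
            id_by_sent.append(ids)
        for a, b in corpus.pairs.get(doc.pmid, set()):
            if a == b:
                continue
            total += 1
            if not any(a in ids and b in ids for ids in id_by_sent):
                cross += 1
    return cross / total if total else 0.0
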