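"""Article corpora: documents, gene-mention annotations and gold interaction pairs.

The unit of input is a PubMed-style citation (PMID, title, abstract). All
character offsets are 0-based half-open intervals into ``full_text``, the
concatenation ``title + " " + abstract`` -- the convention used by PubTator
exports, where abstract annotations continue after the title plus one space.

Gene spans are labeled at the token level with the IOB1 scheme over the tags
``B-GENE``, ``I-GENE`` and ``O``: a span-initial token takes ``I-GENE`` unless
it immediately follows another gene span, in which case ``B-GENE`` marks the
boundary between the two adjacent spans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, TextIO

__all__ = [
    "Provenance",
    "Document",
    "GeneMention",
    "gold_pair",
    "Corpus",
    "LabeledSequence",
    "CorpusError",
    "ParseError",
    "IntegrityError",
    "parse_pubtator",
    "write_pubtator",
    "segment",
    "tokenize_string",
    "project_to_iob",
    "decode_iob",
    "corpus_statistics",
    "read_pairs",
    "write_pairs",
    "canonical_pair",
]

GENE_TAGS = ("B-GENE", "I-GENE", "O")

#: Mention types from annotation files that are kept as gene mentions; all
#: other types (Species, Chemical, Disease, ...) are silently dropped.
GENE_LIKE_TYPES = frozenset({"gene", "geneprotein", "protein", "familyname", "domainmotif"})


class CorpusError(Exception):
    """Base class for corpus-level errors."""


class ParseError(CorpusError):
    """Malformed input line; message names the 1-based line number."""


class IntegrityError(CorpusError):
    """Annotation inconsistent with document text."""


class Provenance(str, Enum):
    GOLD = "gold"
    MODEL = "model"
    LEXICON = "lexicon"
    EXTERNAL = "external"


@dataclass
class Document:
    """One citation: title + abstract, with derived segmentation.

    ``sentences`` and ``tokens`` are filled by :func:`segment`; both index
    into ``full_text``. Every token lies within exactly one sentence and token
    spans are ordered and non-overlapping.
    """

    pmid: str
    title: str
    abstract: str
    sentences: list[tuple[int, int]] = field(default_factory=list)
    tokens: list[list[tuple[int, int]]] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return self.title + " " + self.abstract

    def all_tokens(self) -> list[tuple[int, int]]:
        return [t for sent in self.tokens for t in sent]

    def token_text(self, span: tuple[int, int]) -> str:
        return self.full_text[span[0] : span[1]]


@dataclass(frozen=True)
class GeneMention:
    """A gene-name occurrence as a character span into ``Document.full_text``."""

    start: int
    end: int
    text: str
    provenance: Provenance = Provenance.GOLD
    gene_id: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def validate(self, document: Document) -> None:
        if not (0 <= self.start < self.end <= len(document.full_text)):
            raise IntegrityError(
                f"mention span {self.span} out of bounds for PMID {document.pmid}"
            )
        actual = document.full_text[self.start : self.end]
        if actual != self.text:
            raise IntegrityError(
                f"PMID {document.pmid}: mention text {self.text!r} does not match "
                f"document slice {actual!r} at {self.span}"
            )


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-free representation of a gene-ID pair; self-pairs allowed."""
    return (a, b) if a <= b else (b, a)


def gold_pair(a: str, b: str) -> tuple[str, str]:
    """Alias of :func:`canonical_pair`: pair direction is immaterial."""
    return canonical_pair(a, b)


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    #: pmid -> mentions, sorted by (start, end)
    mentions: dict[str, list[GeneMention]] = field(default_factory=dict)
    #: pmid -> set of canonical unordered ID pairs
    pairs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.documents)

    def document(self, pmid: str) -> Document:
        for d in self.documents:
            if d.pmid == pmid:
                return d
        raise KeyError(pmid)


@dataclass
class LabeledSequence:
    """Tokens of one sentence paired with one IOB1 tag per token."""

    tokens: list[tuple[int, int]]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError("tokens and labels must have equal length")


def is_iob1_valid(labels: Sequence[str]) -> bool:
    """IOB1 validity: B-GENE only immediately after B-GENE or I-GENE."""
    prev = "O"
    for lab in labels:
        if lab not in GENE_TAGS:
            raise ValueError(f"unknown tag {lab!r}")
        if lab == "B-GENE" and prev == "O":
            return False
        prev = lab
    return True


# ---------------------------------------------------------------------------
# Segmentation


_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[\"'(\[]?[A-Z0-9])")
_TOKEN = re.compile(r"[A-Za-z0-9À-ɏ]+|[^\sA-Za-z0-9À-ɏ]")


def _split_sentences(text: str, offset: int) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        end = m.start()
        if end > start:
            spans.append((offset + start, offset + end))
        start = m.end()
    tail = text.rstrip()
    if len(tail) > start:
        spans.append((offset + start, offset + len(tail)))
    return spans


def tokenize_string(text: str, offset: int = 0) -> list[tuple[int, int]]:
    """Rule-based tokenization: alphanumeric runs stay whole ("Shank3" is one
    token), every other non-space character is its own token."""
    return [(offset + m.start(), offset + m.end()) for m in _TOKEN.finditer(text)]


def segment(document: Document) -> Document:
    """Fill sentence and token offsets. Deterministic; the title is always its
    own sentence (it rarely ends with a period)."""
    sentences: list[tuple[int, int]] = []
    if document.title.strip():
        sentences.extend(_split_sentences(document.title, 0))
    abs_off = len(document.title) + 1
    if document.abstract.strip():
        sentences.extend(_split_sentences(document.abstract, abs_off))
    tokens = [
        tokenize_string(document.full_text[s:e], s) for (s, e) in sentences
    ]
    # drop empty sentences (possible with pathological whitespace)
    keep = [(sp, tok) for sp, tok in zip(sentences, tokens) if tok]
    document.sentences = [sp for sp, _ in keep]
    document.tokens = [tok for _, tok in keep]
    return document


# ---------------------------------------------------------------------------
# PubTator-format reading and writing


def parse_pubtator(stream: TextIO | str) -> Corpus:
    """Parse PubTator-style delimited text into a :class:`Corpus`.

    Dialect: ``PMID|t|title`` and ``PMID|a|abstract`` lines, tab-separated
    mention lines ``pmid start end text type [id]`` with offsets over
    title + " " + abstract, tab-separated relation lines
    ``pmid type id1 id2``, and a blank line between documents. Mention lines
    whose type is not gene-like are dropped. Documents are segmented on parse.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    corpus = Corpus()
    cur: dict[str, str] = {}
    cur_mentions: list[tuple[int, GeneMention]] = []
    cur_pairs: set[tuple[str, str]] = set()

    def flush(lineno: int) -> None:
        nonlocal cur, cur_mentions, cur_pairs
        if not cur:
            if cur_mentions or cur_pairs:
                raise ParseError(f"line {lineno}: annotations without a title line")
            return
        if "pmid" not in cur:
            raise ParseError(f"line {lineno}: document block without title line")
        doc = Document(pmid=cur["pmid"], title=cur.get("t", ""), abstract=cur.get("a", ""))
        segment(doc)
        if any(d.pmid == doc.pmid for d in corpus.documents):
            raise ParseError(f"line {lineno}: duplicate PMID {doc.pmid}")
        ments = []
        for ln, m in cur_mentions:
            try:
                m.validate(doc)
            except IntegrityError as exc:
                raise IntegrityError(f"line {ln}: {exc}") from exc
            ments.append(m)
        ments.sort(key=lambda m: (m.start, m.end))
        corpus.documents.append(doc)
        corpus.mentions[doc.pmid] = ments
        corpus.pairs[doc.pmid] = cur_pairs
        cur, cur_mentions, cur_pairs = {}, [], set()

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        if "|" in line and "\t" not in line.split("|", 1)[0]:
            parts = line.split("|", 2)
            if len(parts) == 3 and parts[1] in ("t", "a"):
                pmid, kind, text = parts
                if cur.get("pmid") not in (None, pmid):
                    raise ParseError(f"line {lineno}: PMID changed mid-block")
                if kind in cur:
                    raise ParseError(f"line {lineno}: duplicate |{kind}| line")
                cur["pmid"] = pmid
                cur[kind] = text
                continue
        if "\t" in line:
            cols = line.split("\t")
            if len(cols) in (5, 6) and cols[1].isdigit() and cols[2].isdigit():
                pmid, start, end, text, mtype = cols[:5]
                if cur.get("pmid") not in (None, pmid):
                    raise ParseError(f"line {lineno}: mention PMID mismatch")
                cur.setdefault("pmid", pmid)
                if mtype.lower() not in GENE_LIKE_TYPES:
                    continue
                gid = cols[5] if len(cols) == 6 and cols[5] not in ("", "-") else None
                cur_mentions.append(
                    (
                        lineno,
                        GeneMention(
                            int(start), int(end), text, Provenance.GOLD, gid
                        ),
                    )
                )
                continue
            if len(cols) == 4:
                pmid, _rtype, id1, id2 = cols
                if cur.get("pmid") not in (None, pmid):
                    raise ParseError(f"line {lineno}: relation PMID mismatch")
                cur.setdefault("pmid", pmid)
                cur_pairs.add(canonical_pair(id1, id2))
                continue
        raise ParseError(f"line {lineno}: malformed line {line!r}")
    flush(len(lines) + 1)
    return corpus


def write_pubtator(corpus: Corpus) -> str:
    """Canonical serialization; ``parse_pubtator`` round-trips its output."""
    out: list[str] = []
    for doc in corpus.documents:
        out.append(f"{doc.pmid}|t|{doc.title}")
        out.append(f"{doc.pmid}|a|{doc.abstract}")
        for m in sorted(corpus.mentions.get(doc.pmid, []), key=lambda m: (m.start, m.end)):
            gid = m.gene_id if m.gene_id is not None else "-"
            out.append(f"{doc.pmid}\t{m.start}\t{m.end}\t{m.text}\tGene\t{gid}")
        for a, b in sorted(corpus.pairs.get(doc.pmid, set())):
            out.append(f"{doc.pmid}\tPPIm\t{a}\t{b}")
        out.append("")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# IOB projection / decoding


def snap_to_tokens(
    document: Document, mention: GeneMention
) -> tuple[int, int] | None:
    """Token-index range (sentence-flattened) covering the mention, snapping
    boundaries that fall inside a token *outward* (never truncating the
    mention text). Returns None when the mention covers no token."""
    toks = document.all_tokens()
    first = last = None
    for i, (s, e) in enumerate(toks):
        if e > mention.start and s < mention.end:  # overlap
            if first is None:
                first = i
            last = i
    if first is None:
        return None
    return first, last


def project_to_iob(
    document: Document, mentions: Sequence[GeneMention]
) -> list[LabeledSequence]:
    """Project mention spans to per-sentence IOB1 tag sequences.

    The first token of a span takes ``I-GENE`` unless the immediately
    preceding token ends a gene span, in which case ``B-GENE``. Overlapping
    mentions are an error; the caller resolves them first.
    """
    toks = document.all_tokens()
    owner = [-1] * len(toks)  # mention index owning each token
    for mi, m in enumerate(sorted(mentions, key=lambda m: (m.start, m.end))):
        rng = snap_to_tokens(document, m)
        if rng is None:
            continue
        a, b = rng
        for i in range(a, b + 1):
            if owner[i] != -1:
                raise ValueError(
                    f"overlapping mentions at token {i} in PMID {document.pmid}"
                )
            owner[i] = mi

    labels = ["O"] * len(toks)
    for i in range(len(toks)):
        if owner[i] == -1:
            continue
        starts_span = i == 0 or owner[i - 1] != owner[i]
        prev_is_gene = i > 0 and owner[i - 1] != -1
        if starts_span and prev_is_gene:
            labels[i] = "B-GENE"
        else:
            labels[i] = "I-GENE"

    out: list[LabeledSequence] = []
    pos = 0
    for sent_toks in document.tokens:
        n = len(sent_toks)
        out.append(LabeledSequence(list(sent_toks), labels[pos : pos + n]))
        pos += n
    return out


def decode_iob(
    seq: LabeledSequence, document: Document, provenance: Provenance = Provenance.MODEL
) -> list[GeneMention]:
    """Decode an IOB1 label sequence back to maximal contiguous gene spans.

    Invalid inputs are repaired first (a stray B-GENE becomes I-GENE) so the
    decoder never crashes on raw model output.
    """
    from .augment import repair_iob  # local import to avoid a cycle

    labels = repair_iob(seq.labels)
    mentions: list[GeneMention] = []
    span_start: int | None = None

    def close(end_tok: int) -> None:
        nonlocal span_start
        if span_start is None:
            return
        s = seq.tokens[span_start][0]
        e = seq.tokens[end_tok][1]
        mentions.append(
            GeneMention(s, e, document.full_text[s:e], provenance)
        )
        span_start = None

    for i, lab in enumerate(labels):
        if lab == "O":
            close(i - 1)
        elif lab == "B-GENE":
            close(i - 1)
            span_start = i
        else:  # I-GENE
            if span_start is None:
                span_start = i
    close(len(labels) - 1)
    return mentions


# ---------------------------------------------------------------------------
# Statistics and pair-set I/O


@dataclass(frozen=True)
class CorpusStatistics:
    n_articles: int
    n_pairs: int
    mean_pairs_per_article: float

    @property
    def mean_rounded(self) -> float:
        return round(self.mean_pairs_per_article, 2)


def corpus_statistics(corpus: Corpus) -> CorpusStatistics:
    """Article and relevant-pair totals with the mean pairs per article
    (reported to 2 decimals alongside the exact value)."""
    n = len(corpus.documents)
    if n == 0:
        raise CorpusError("empty corpus")
    n_pairs = sum(len(p) for p in corpus.pairs.values())
    return CorpusStatistics(n, n_pairs, n_pairs / n)


def read_pairs(stream: TextIO | str) -> dict[str, set[tuple[str, str]]]:
    """Read prediction/gold TSV ``pmid<TAB>id1<TAB>id2``; duplicates collapse."""
    text = stream if isinstance(stream, str) else stream.read()
    out: dict[str, set[tuple[str, str]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError(f"line {lineno}: expected 3 columns, got {len(cols)}")
        pmid, a, b = cols
        out.setdefault(pmid, set()).add(canonical_pair(a, b))
    return out


def write_pairs(pairs: dict[str, set[tuple[str, str]] | Iterable[tuple[str, str]]]) -> str:
    """Serialize pair sets; each pair written with id1 <= id2 lexicographically."""
    lines = []
    for pmid in sorted(pairs):
        for a, b in sorted(canonical_pair(*p) for p in pairs[pmid]):
            lines.append(f"{pmid}\t{a}\t{b}")
    return "\n".join(lines) + ("\n" if lines else "")
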