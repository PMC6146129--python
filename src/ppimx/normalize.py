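"""Knowledge-based gene normalization: mention string + document -> gene ID.

A mention is resolved by intersecting a relevance-ranked candidate list for
the mention string (``gene_name_lookup``) with document-level gene-ID sets:
first the primary per-article index (the gene-database annotations for the
PMID), then a secondary fallback index (document-level annotations from a
tagging service). The first candidate, in rank order, found in the primary
set wins; only if none is found is the fallback consulted; otherwise the
result is null and the span is dropped from the pipeline. Sequential
primary-then-fallback consultation showed a slight advantage over a plain
union in the original experiments; a union mode is kept behind a switch.

All lookups are served from a :class:`KnowledgeBundle` of plain tables so
runs are reproducible without network access; an optional live NCBI
E-utilities adapter with on-disk caching implements the same interface.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

from .corpus import Document, GeneMention

__all__ = [
    "KnowledgeBundle",
    "BackendError",
    "gene_name_lookup",
    "gene_pmid_lookup",
    "pubtator_pmid_lookup",
    "normalize_mention",
    "normalize_document",
    "load_bundle",
    "save_bundle",
    "clean_mention",
    "CachedLookup",
    "build_esearch_url",
    "EUtilsNameLookup",
]

#: ranked candidate lists are truncated at this many IDs (mirrors the
#: ``retmax=100`` of the reference gene-database query).
MAX_CANDIDATES = 100


class BackendError(RuntimeError):
    """A lookup backend failed (retryable); distinct from 'no candidates'."""


@dataclass
class KnowledgeBundle:
    """Lookup tables backing normalization.

    name_index: mention string -> ranked, duplicate-free candidate gene IDs.
    doc_primary / doc_fallback: PMID -> document-level gene-ID sets.
    lexicon: gene name -> IDs (used by the NER lexicon scan).
    homolog_map: gene ID -> homology-group ID.
    """

    name_index: dict[str, list[str]] = field(default_factory=dict)
    doc_primary: dict[str, set[str]] = field(default_factory=dict)
    doc_fallback: dict[str, set[str]] = field(default_factory=dict)
    lexicon: dict[str, list[str]] = field(default_factory=dict)
    homolog_map: dict[str, str] = field(default_factory=dict)
    #: optional live backends: callables raising BackendError on failure
    name_backend: Callable[[str], list[str]] | None = None
    primary_backend: Callable[[str], set[str]] | None = None
    fallback_backend: Callable[[str], set[str]] | None = None
    #: consult fallback only when primary yields nothing ("sequential"),
    #: or merge both sets ("union")
    mode: str = "sequential"

    def __post_init__(self) -> None:
        if self.mode not in ("sequential", "union"):
            raise ValueError("mode must be 'sequential' or 'union'")


_PUNCT_FLANK = "\"'()[]{}.,;:!?*"


def clean_mention(text: str) -> str:
    """Whitespace-normalize and strip flanking punctuation before lookup."""
    return " ".join(text.split()).strip(_PUNCT_FLANK).strip()


def gene_name_lookup(kb: KnowledgeBundle, mention: str) -> list[str]:
    """Ranked candidate gene IDs for a mention string (possibly empty).

    Case-sensitive lookup first, case-insensitive retry second; at most
    ``MAX_CANDIDATES`` results, duplicate-free.
    """
    key = clean_mention(mention)
    if not key:
        raise ValueError("empty mention")
    ranked = kb.name_index.get(key)
    if ranked is None:
        lower = key.lower()
        for name, ids in kb.name_index.items():
            if name.lower() == lower:
                ranked = ids
                break
    if ranked is None and kb.name_backend is not None:
        ranked = kb.name_backend(key)
    if ranked is None:
        return []
    seen: set[str] = set()
    out: list[str] = []
    for gid in ranked:
        if gid not in seen:
            seen.add(gid)
            out.append(gid)
    return out[:MAX_CANDIDATES]


def gene_pmid_lookup(kb: KnowledgeBundle, pmid: str) -> set[str]:
    """Primary document-level candidate gene IDs for a PMID."""
    ids = kb.doc_primary.get(pmid)
    if ids is None and kb.primary_backend is not None:
        ids = kb.primary_backend(pmid)
    return set(ids) if ids else set()


def pubtator_pmid_lookup(kb: KnowledgeBundle, pmid: str) -> set[str]:
    """Secondary (fallback) document-level gene IDs for a PMID."""
    ids = kb.doc_fallback.get(pmid)
    if ids is None and kb.fallback_backend is not None:
        ids = kb.fallback_backend(pmid)
    return set(ids) if ids else set()


def normalize_mention(kb: KnowledgeBundle, mention: str, pmid: str) -> str | None:
    """Resolve one mention to a gene ID, or None (span is then dropped).

    1. C <- gene_name_lookup(mention); empty -> None.
    2. First c in C (rank order) with c in the primary document set, if any.
    3. Else first c in C in the fallback document set.
    4. Else None.
    """
    if not clean_mention(mention):
        return None  # nothing lookupable (e.g. bare punctuation)
    candidates = gene_name_lookup(kb, mention)
    if not candidates:
        return None
    primary = gene_pmid_lookup(kb, pmid)
    fallback = pubtator_pmid_lookup(kb, pmid)
    if kb.mode == "union":
        allowed = primary | fallback
        for c in candidates:
            if c in allowed:
                return c
        return None
    for c in candidates:
        if c in primary:
            return c
    for c in candidates:
        if c in fallback:
            return c
    return None


def normalize_document(
    kb: KnowledgeBundle, document: Document, mentions: Sequence[GeneMention]
) -> list[GeneMention]:
    """Normalize each mention independently; null-mapped mentions are removed.
    The document's candidate set is the set of distinct surviving IDs."""
    out: list[GeneMention] = []
    for m in mentions:
        gid = normalize_mention(kb, m.text, document.pmid)
        if gid is not None:
            out.append(replace(m, gene_id=gid))
    return out


# ---------------------------------------------------------------------------
# Bundle files


def _read_tsv(path: str) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        return [line.split("\t") for line in fh.read().splitlines() if line.strip()]


def load_bundle(directory: str) -> KnowledgeBundle:
    """Load a fixture bundle: ``names.tsv`` (name, rank, gene_id),
    ``doc_primary.tsv`` / ``doc_fallback.tsv`` (pmid, gene_id),
    ``lexicon.tsv`` (name, comma-separated ids), ``homologs.tsv``
    (group, gene_id)."""
    kb = KnowledgeBundle()
    ranked: dict[str, list[tuple[int, str]]] = {}
    for name, rank, gid in _read_tsv(os.path.join(directory, "names.tsv")):
        ranked.setdefault(name, []).append((int(rank), gid))
    for name, pairs in ranked.items():
        kb.name_index[name] = [g for _, g in sorted(pairs)]
    for fname, target in (("doc_primary.tsv", kb.doc_primary),
                          ("doc_fallback.tsv", kb.doc_fallback)):
        path = os.path.join(directory, fname)
        if os.path.exists(path):
            for pmid, gid in _read_tsv(path):
                target.setdefault(pmid, set()).add(gid)
    lex_path = os.path.join(directory, "lexicon.tsv")
    if os.path.exists(lex_path):
        for name, ids in _read_tsv(lex_path):
            kb.lexicon[name] = ids.split(",")
    hom_path = os.path.join(directory, "homologs.tsv")
    if os.path.exists(hom_path):
        for group, gid in _read_tsv(hom_path):
            kb.homolog_map[gid] = group
    return kb


def save_bundle(kb: KnowledgeBundle, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)

    def write(fname: str, rows: list[tuple[str, ...]]) -> None:
        with open(os.path.join(directory, fname), "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write("\t".join(row) + "\n")

    write("names.tsv", [(n, str(r), g) for n in sorted(kb.name_index)
                        for r, g in enumerate(kb.name_index[n])])
    write("doc_primary.tsv", [(p, g) for p in sorted(kb.doc_primary)
                              for g in sorted(kb.doc_primary[p])])
    write("doc_fallback.tsv", [(p, g) for p in sorted(kb.doc_fallback)
                               for g in sorted(kb.doc_fallback[p])])
    write("lexicon.tsv", [(n, ",".join(kb.lexicon[n])) for n in sorted(kb.lexicon)])
    write("homologs.tsv", sorted((grp, gid) for gid, grp in kb.homolog_map.items()))


# ---------------------------------------------------------------------------
# Caching and the optional live adapter


class CachedLookup:
    """Memoize a lookup callable; counts backend calls (for tests and for
    polite use of rate-limited services). Optional on-disk JSON cache."""

    def __init__(
        self,
        fn: Callable[[str], list | set],
        cache_dir: str | None = None,
        namespace: str = "lookup",
    ) -> None:
        self.fn = fn
        self.cache: dict[str, list | set] = {}
        self.calls = 0
        self.cache_dir = cache_dir
        self.namespace = namespace
        if cache_dir:
            os.makedirs(cache_dir, exist_ok=True)

    def _disk_path(self, key: str) -> str:
        h = hashlib.sha1(f"{self.namespace}:{key}".encode()).hexdigest()
        return os.path.join(self.cache_dir, f"{h}.json")  # type: ignore[arg-type]

    def __call__(self, key: str):
        if key in self.cache:
            return self.cache[key]
        if self.cache_dir:
            path = self._disk_path(key)
            if os.path.exists(path):
                with open(path, encoding="utf-8") as fh:
                    val = json.load(fh)
                self.cache[key] = val
                return val
        self.calls += 1
        val = self.fn(key)
        self.cache[key] = val
        if self.cache_dir:
            with open(self._disk_path(key), "w", encoding="utf-8") as fh:
                json.dump(sorted(val) if isinstance(val, set) else list(val), fh)
        return val


def build_esearch_url(term: str, db: str = "gene", retmax: int = MAX_CANDIDATES,
                      sort: str = "relevance") -> str:
    """Documented query shape of the NCBI E-utilities gene search."""
    params = {"db": db, "term": term, "retmax": str(retmax), "sort": sort}
    return (
        "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi?"
        + urllib.parse.urlencode(params)
    )


class EUtilsNameLookup:
    """Live gene_name_lookup adapter (optional; never used by the tests).

    Queries the NCBI gene database, rate-limited, with on-disk caching.
    """

    def __init__(self, cache_dir: str | None = None, min_interval: float = 0.34) -> None:
        self.min_interval = min_interval
        self._last = 0.0
        self._cached = CachedLookup(self._fetch, cache_dir, "esearch_gene")

    def _fetch(self, term: str) -> list[str]:
        import xml.etree.ElementTree as ET

        wait = self.min_interval - (time.monotonic() - self._last)
        if wait > 0:
            time.sleep(wait)
        self._last = time.monotonic()
        try:
            with urllib.request.urlopen(build_esearch_url(term), timeout=30) as resp:
                tree = ET.parse(resp)
        except Exception as exc:  # noqa: BLE001 - network failure is retryable
            raise BackendError(f"esearch failed for {term!r}: {exc}") from exc
        return [e.text for e in tree.getroot().iter("Id") if e.text]

    def __call__(self, term: str) -> list[str]:
        return self._cached(term)
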