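"""Document-level scoring of predicted gene-ID pair sets against gold sets.

Two matching criteria are supported: exact gene-ID matching, and homology
matching where gene IDs in the same homology group (e.g. NCBI HomoloGene)
are treated as interchangeable. Micro scores pool true/false positives and
false negatives over all documents; macro (example-based) scores compute
per-document precision/recall/F1 and average them across documents.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from .corpus import ParseError, canonical_pair

__all__ = [
    "HomologMap",
    "canonicalize_pair",
    "micro_scores",
    "macro_scores",
    "load_homolog_map",
    "Scores",
]

#: gene ID -> homology-group ID; IDs absent from the map canonicalize to themselves.
HomologMap = Mapping[str, str]


@dataclass(frozen=True)
class Scores:
    precision: float
    recall: float
    f1: float


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def canonicalize_pair(
    pair: tuple[str, str], homolog_map: HomologMap | None = None
) -> tuple[str, str]:
    """Order-free (sorted) pair, with each ID replaced by its homology-group
    ID when a map is given; unmapped IDs stand for themselves."""
    a, b = pair
    if homolog_map is not None:
        a = homolog_map.get(a, a)
        b = homolog_map.get(b, b)
    return canonical_pair(a, b)


def _canon_set(
    pairs: Iterable[tuple[str, str]], homolog_map: HomologMap | None
) -> set[tuple[str, str]]:
    # deduplicate after canonicalization: homolog collisions merge
    return {canonicalize_pair(p, homolog_map) for p in pairs}


def _check_keys(gold: Mapping, pred: Mapping) -> None:
    if set(gold) != set(pred):
        missing = set(gold) ^ set(pred)
        raise ValueError(f"gold/prediction document keys differ: {sorted(missing)[:5]}")


def micro_scores(
    gold: Mapping[str, set[tuple[str, str]]],
    pred: Mapping[str, set[tuple[str, str]]],
    homolog_map: HomologMap | None = None,
) -> Scores:
    """Micro precision/recall/F1 pooled over all documents."""
    _check_keys(gold, pred)
    tp = fp = fn = 0
    for pmid in gold:
        g = _canon_set(gold[pmid], homolog_map)
        p = _canon_set(pred[pmid], homolog_map)
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return Scores(prec, rec, _f1(prec, rec))


def macro_scores(
    gold: Mapping[str, set[tuple[str, str]]],
    pred: Mapping[str, set[tuple[str, str]]],
    homolog_map: HomologMap | None = None,
) -> Scores:
    """Example-based scores: per-document P/R/F1 averaged across documents.

    A document with empty gold and empty prediction counts as a vacuous
    success (P = R = F1 = 1); empty gold against a nonempty prediction
    scores 0. Gold sets are nonempty in the task itself, so this only affects
    synthetic edge cases.
    """
    _check_keys(gold, pred)
    if not gold:
        raise ValueError("no documents to score")
    ps, rs, fs = [], [], []
    for pmid in gold:
        g = _canon_set(gold[pmid], homolog_map)
        p = _canon_set(pred[pmid], homolog_map)
        if not g and not p:
            ps.append(1.0)
            rs.append(1.0)
            fs.append(1.0)
            continue
        tp = len(g & p)
        prec = tp / len(p) if p else 0.0
        rec = tp / len(g) if g else 0.0
        ps.append(prec)
        rs.append(rec)
        fs.append(_f1(prec, rec))
    n = len(gold)
    return Scores(sum(ps) / n, sum(rs) / n, sum(fs) / n)


def load_homolog_map(stream: TextIO | str) -> dict[str, str]:
    """Read a homology table into ``gene ID -> group ID``.

    Accepts either 2-column TSV ``group<TAB>gene_id`` or the 6-column
    homologene.data layout (group, taxid, gene id, symbol, protein gi,
    protein accession), using columns 1 and 3.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(stream.read().splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) == 2:
            group, gene = cols
        elif len(cols) >= 3:
            group, gene = cols[0], cols[2]
        else:
            raise ParseError(f"line {lineno}: expected 2 or >=3 columns")
        mapping[gene.strip()] = group.strip()
    return mapping
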