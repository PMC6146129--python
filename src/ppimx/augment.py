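"""Annotation augmentation: merging tool-produced gene mentions into a
gold-annotated corpus, and repairing tag sequences to valid IOB1.

Gold mention annotations in relation-extraction corpora are typically
incomplete -- only genes participating in a relation are annotated -- which
sends mixed signals to a sequence tagger. Document-level annotations from an
external tool (e.g. a GNormPlus/PubTator export read through
:func:`ppimx.corpus.parse_pubtator`) are merged in wherever they fall on
tokens that are currently all labeled O.
"""

from __future__ import annotations

from typing import Sequence

from .corpus import Document, GeneMention, Provenance, snap_to_tokens

__all__ = ["merge_external_annotations", "repair_iob", "is_iob1_valid"]

from .corpus import is_iob1_valid  # re-export: the validity predicate lives with the tags


def merge_external_annotations(
    document: Document,
    gold: Sequence[GeneMention],
    external: Sequence[GeneMention],
) -> list[GeneMention]:
    """Insert external mentions whose covered tokens are all currently O.

    Overlap is decided at token granularity: an external mention sharing even
    one token with a gold mention (or a previously accepted external one) is
    discarded. Gold mentions are never removed; accepted externals keep
    ``provenance=external``. The result is sorted and non-overlapping.
    """
    taken: set[int] = set()
    for m in gold:
        rng = snap_to_tokens(document, m)
        if rng is not None:
            taken.update(range(rng[0], rng[1] + 1))

    merged = list(gold)
    for m in sorted(external, key=lambda m: (m.start, m.end)):
        rng = snap_to_tokens(document, m)
        if rng is None:
            continue
        covered = set(range(rng[0], rng[1] + 1))
        if covered & taken:
            continue
        taken.update(covered)
        merged.append(
            GeneMention(m.start, m.end, m.text, Provenance.EXTERNAL, m.gene_id)
        )
    merged.sort(key=lambda m: (m.start, m.end))
    return merged


def repair_iob(labels: Sequence[str]) -> list[str]:
    """Minimal correction to a valid IOB1 sequence.

    A ``B-GENE`` that is not immediately preceded by a gene tag cannot mark a
    boundary between adjacent spans, so it becomes ``I-GENE``; every other tag
    is left unchanged. Idempotent.
    """
    out: list[str] = []
    prev = "O"
    for lab in labels:
        if lab not in ("B-GENE", "I-GENE", "O"):
            raise ValueError(f"unknown tag {lab!r}")
        if lab == "B-GENE" and prev == "O":
            lab = "I-GENE"
        out.append(lab)
        prev = lab
    return out
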