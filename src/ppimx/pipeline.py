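"""End-to-end extraction: tag gene mentions, add lexicon matches, normalize
to gene IDs, classify all candidate ID pairs, decide the document's pairs.

The input is one article (title + abstract); the output is a set of unordered
gene-ID pairs. Per-document failures never abort a corpus run: the document
is marked failed and the run report carries a nonzero failure count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus import Corpus, Document, segment
from .ner import NerEnsemble, lexicon_scan, tag_document
from .normalize import KnowledgeBundle, normalize_document
from .relation import RcEnsemble, generate_instances, pair_scores, predict_pairs

__all__ = ["extract_document", "run_corpus", "RunReport", "StageCounts"]

logger = logging.getLogger(__name__)


@dataclass
class StageCounts:
    tagged: int = 0
    lexicon_added: int = 0
    normalized: int = 0
    dropped_null: int = 0
    candidates: int = 0
    predicted_pairs: int = 0

    def check(self) -> None:
        """Accounting identity: every mention entering normalization either
        survives with an ID or is dropped."""
        if self.normalized + self.dropped_null != self.tagged + self.lexicon_added:
            raise AssertionError("stage counts do not balance")

    def __iadd__(self, other: "StageCounts") -> "StageCounts":
        for f in ("tagged", "lexicon_added", "normalized", "dropped_null",
                  "candidates", "predicted_pairs"):
            setattr(self, f, getattr(self, f) + getattr(other, f))
        return self


@dataclass
class RunReport:
    counts: StageCounts = field(default_factory=StageCounts)
    n_documents: int = 0
    failed_pmids: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failed_pmids


def extract_document(
    document: Document,
    ner_ensemble: NerEnsemble,
    kb: KnowledgeBundle,
    rc_ensemble: RcEnsemble,
    use_lexicon: bool = True,
    counts: StageCounts | None = None,
) -> set[tuple[str, str]]:
    """Run the full pipeline on one document. Returns at least one pair
    whenever any mention normalizes to a candidate ID, else the empty set."""
    if not document.sentences:
        segment(document)
    counts = counts if counts is not None else StageCounts()

    mentions = tag_document(ner_ensemble, document)
    counts.tagged += len(mentions)
    if use_lexicon and kb.lexicon:
        extra = lexicon_scan(document, kb.lexicon, mentions)
        counts.lexicon_added += len(extra)
        mentions = sorted(mentions + extra, key=lambda m: (m.start, m.end))
    normalized = normalize_document(kb, document, mentions)
    counts.normalized += len(normalized)
    counts.dropped_null += len(mentions) - len(normalized)

    instances = generate_instances(document, normalized)
    counts.candidates += len({m.gene_id for m in normalized})
    pairs = predict_pairs(rc_ensemble, instances)
    counts.predicted_pairs += len(pairs)
    return pairs


def run_corpus(
    corpus: Corpus,
    ner_ensemble: NerEnsemble,
    kb: KnowledgeBundle,
    rc_ensemble: RcEnsemble,
    use_lexicon: bool = True,
) -> tuple[dict[str, set[tuple[str, str]]], RunReport]:
    """Apply :func:`extract_document` to every article; returns per-document
    predictions and a run report with per-stage counts."""
    report = RunReport()
    predictions: dict[str, set[tuple[str, str]]] = {}
    for doc in corpus.documents:
        report.n_documents += 1
        try:
            predictions[doc.pmid] = extract_document(
                doc, ner_ensemble, kb, rc_ensemble, use_lexicon, report.counts
            )
        except Exception:  # noqa: BLE001 - a bad document must not kill the run
            logger.exception("extraction failed for PMID %s", doc.pmid)
            report.failed_pmids.append(doc.pmid)
            predictions[doc.pmid] = set()
    report.counts.check()
    return predictions, report
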