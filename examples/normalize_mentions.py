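"""Resolve gene mentions to gene IDs with document-level knowledge.

Shows the three outcomes of the normalization algorithm on a hand-built
knowledge bundle: a candidate confirmed by the primary per-article index, one
recovered through the secondary fallback index, and a lexicon false positive
("novel") that no document index supports and that is therefore dropped.
"""

from ppimx.normalize import KnowledgeBundle, normalize_mention

kb = KnowledgeBundle(
    # mention string -> candidate gene IDs ranked by relevance
    name_index={
        "Shank3": ["85358", "59312"],   # human variant ranked first, then rat
        "Sharpin": ["81858"],
        "novel": ["441282"],
    },
    # PMID -> gene IDs the primary knowledge source lists for the article
    doc_primary={"23897824": {"59312"}},
    # PMID -> document-level fallback annotations
    doc_fallback={"23897824": {"81858", "59312"}},
)

for mention in ("Shank3", "Sharpin", "novel"):
    gid = normalize_mention(kb, mention, "23897824")
    print(f"{mention:10s} -> {gid}")
# Shank3 resolves to 59312: the rat variant is the one the article's primary
# index supports, even though the human ID ranks first in the name lookup.
# Sharpin is absent from the primary index and comes back via the fallback.
# "novel" has a candidate but no document support: null, dropped downstream.
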