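# Methods

This note documents the models and procedures implemented in `ppimx`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would want spelled
out.

## Task and pipeline

The unit of extraction is one citation (PMID, title, abstract) and the output
is a set of *unordered* gene-ID pairs participating in a protein–protein
interaction affected by a genetic mutation. Self-pairs (a protein interacting
with itself) are legal, direction is immaterial, and a pair's two mentions
may occur in different sentences — which is why relation decisions are made
at the document level rather than per sentence. Three stages run in order:
mention tagging, normalization to gene IDs, and pair classification. The
stages are strict interfaces: each can be replaced or ablated independently
(the lexicon-ablation switch in `pipeline.run_corpus` is an example).

## Gene-mention tagger (`ppimx.ner`)

**Architecture.** A CNN–LSTM hybrid sequence labeler. For a word, the
lowercased character sequence is embedded (characters, dimension α = 32) and
concatenated row-wise with character-*type* embeddings (dimension 8 over the
four types lowercase / uppercase / punctuation / other, so digits are
"other"); a window-3 convolution with κ = 50 filters plus ReLU and
max-over-time pooling yields the character-composed word vector **u**
(length κ). The tagger input per token is **u** ∥ word embedding (d = 200) ∥
word-type embedding (dimension 32 over all-lower / mixed / cap-first /
all-upper / other), giving 282 features into a bidirectional LSTM with
π = 200 units per direction. Each position's concatenated state (2π = 400)
passes through a dense layer to m = 3 logits and a softmax over the IOB1
tags. Case information is carried *only* by the type embeddings, since
characters are lowercased before lookup.

**IOB1.** Span-initial tokens take I-GENE by default; B-GENE marks only the
boundary between two adjacent gene spans. `repair_iob` turns any B-GENE not
preceded by a gene tag into I-GENE (the minimal edit) and is idempotent;
decoding always repairs first, so the decoder cannot crash on raw model
output.

**Loss.** Mean per-token categorical cross-entropy per sentence, averaged
over the minibatch. The training path uses a fused softmax–cross-entropy op;
`sequence_loss` implements the textbook formula and the tests assert the two
routes agree to 1e-9.

**Training.** SGD, minibatches of 20 sentences, at most 10 000 iterations,
checkpoint every 100 iterations on development-set *span* F1 (token-level F1
would reward partial spans; span-level matches how mentions are consumed
downstream), early stopping after 10 checkpoints without improvement, and an
exponential learning-rate decay of 0.95 applied at each checkpoint. The
initial learning rate is 0.5 and config-exposed: with plain SGD (no
momentum) and this objective, small rates (≲0.1) stall in the all-O
plateau — the tagger predicts the majority tag everywhere and the loss
plateaus before any span is ever emitted — so the default is chosen as the
smallest round value that reliably escapes it on the reduced problems;
gradient clipping at global norm 5.0 keeps the LSTM stable at that rate.
Forget-gate biases initialize to 1, dense/recurrent weights use
Glorot-uniform, embeddings uniform ±0.05 (word vectors in word2vec text
format override rows when provided).

**Ensembling.** 10 members (default), each trained on an independent random
50% of the sentences with a distinct seed; the complementary 50% serves as
that member's development set, which both regularizes (each member sees less
data) and supplies checkpoint selection without a dedicated held-out split.
Prediction averages the per-token class distributions across members, takes
the argmax, repairs to valid IOB1 and decodes to character spans. Averaging
distributions (rather than voting on tags) makes the ensemble a single
well-defined probabilistic model and is what the tests' brute-force oracle
assumes.

**Lexicon post-processing.** After tagging, the document text is scanned for
gene names from a name→IDs lexicon: case-insensitive, anchored at token
boundaries, candidates ranked longest-first (ties leftmost) and accepted
greedily when they do not overlap a tagged or previously accepted span. This
deliberately trades precision for recall; the false positives it introduces
("novel", "ligand") are expected to fail normalization for lack of document
support and vanish from the pipeline.

**Annotation augmentation.** Relation corpora annotate only genes that
participate in a relation, so the same surface form can appear labeled and
unlabeled — mixed signals for a tagger. `merge_external_annotations` inserts
document-level mentions from an external tagging tool wherever all covered
tokens are currently O; overlap is decided at token granularity and gold
mentions are never displaced.

**Unicode.** Text is never rewritten (annotation offsets are defined over the
raw title+abstract), but at feature level non-ASCII characters fold to ASCII
equivalents where a single-character NFKD mapping exists (α → a), so
mentions like *α-fodrin* are representable without any offset bookkeeping.

## Gene normalization (`ppimx.normalize`)

The algorithm takes a mention string and a PMID and returns a gene ID or
null:

1. `gene_name_lookup` → relevance-ranked candidate IDs (≤ 100, mirroring the
   reference query's `retmax`); empty → null.
2. First candidate, in rank order, contained in the article's primary
   document-level gene set (`gene_pmid_lookup`).
3. Otherwise first candidate in the secondary fallback set
   (`pubtator_pmid_lookup`).
4. Otherwise null; the span is dropped.

Primary-then-fallback is sequential, not a union — the sequential order
showed a slight advantage in the original experiments — but
`KnowledgeBundle(mode="union")` switches to the union. Mentions are
whitespace-normalized and stripped of flanking punctuation; lookup is
case-sensitive first with a case-insensitive retry. All lookups are served
from plain tables (`KnowledgeBundle`) so runs are offline and deterministic;
a live NCBI E-utilities adapter with on-disk caching and rate limiting
implements the same callable interface but is never exercised by tests.

## Relation classifier (`ppimx.relation`)

**Instances.** For candidate-ID set G (the distinct IDs surviving
normalization), each unordered pair {A, B}, A ≠ B, yields two instances —
orders (A, B) and (B, A) — with A's mentions replaced by GENE_A, B's by
GENE_B; each candidate also yields one self-pair instance using GENE_S; in
every instance, mentions of all other candidates become GENE_N. That is |G|²
instances per document, and no candidate's surface string survives blinding
(the classifier learns context, not names). A mention's whole token run
collapses to a single placeholder token; overlapping normalized spans are
resolved longest-first. Instances are capped at 1 500 tokens, truncated from
the end but never past the first occurrence of a bound token — abstracts do
not approach this in practice.

**Architecture.** Word embeddings (d = 200) over the blinded token sequence;
parallel convolutions with windows 3/4/5 and 200 filters each, ReLU,
max-over-time pooling (pooled vector 600), dropout 0.5, dense layer to a
2-way softmax; the "score" of an instance is the positive-class probability.
Four all-zero padding vectors (a frozen zero embedding row) surround the text
and separate sentences so every window position is defined even for 1-token
inputs.

**Training.** RMSProp (lr 0.001, ρ = 0.9), batch size 8, 30 epochs,
checkpoint per epoch keeping the best development F1. Each of the 10 ensemble
members uses an independent random 80/20 split and seed. The split is at
*document* level and the development metric is *pair-level* F1 computed with
inference semantics (both orders averaged, threshold + fallback), so
checkpoint selection optimizes exactly the quantity the pipeline reports.

**Decision rule.** A pair is positive when its mean probability over all
members and both orders exceeds 0.5 (strictly); if no pair qualifies and
candidates exist, the single highest-scoring pair is emitted (ties broken by
lexicographically smallest canonical pair), matching the task guarantee that
every relevant article contains at least one pair.

## Evaluation (`ppimx.evaluation`)

Micro scores pool TP/FP/FN over documents; macro (example-based) scores
average per-document P, R and F1. Under homology matching each gene ID is
first replaced by its homology-group ID (IDs absent from the map stand for
themselves) and both gold and predicted sets are deduplicated *after*
canonicalization; since canonicalization only merges equivalence classes,
homolog scores are never below exact scores. Degenerate conventions: P = 0
with no predictions, R = 0 with no gold, per-document F1 = 1 when both sets
are empty (vacuous success; real data guarantees nonempty gold). The scorer
is verified against an independent brute-force implementation on 1 000
random configurations.

## Synthetic data (`ppimx.fixtures`)

The generator emits templated abstracts with the statistical structure the
pipeline assumes: every article has ≥ 1 gold pair; positive pairs co-occur
with a lexical cue ("interacts with", "promotes sumoylation of", "binds",
"forms homodimers") plus a mutation phrase; negative gene co-occurrences
carry no cue; a configurable fraction of non-self pairs is expressed across
sentence boundaries (no sentence contains both participants); gene names mix
case/digit shapes ("Xbp7", "TRK9", "abc-1") to exercise the character- and
word-type features. Defaults: 100 articles (60/20/20 train/dev/test), 40
genes, cross-sentence fraction 0.25, self-interaction fraction 0.10, homolog
confuser rate 0.10 (one name shared by two IDs in the same homology group —
the human/rat ambiguity), lexicon-only rate 0.15, 2 distractor IDs per
document index, 50-dim random word vectors. Everything derives from one seed
and regeneration is byte-identical.

Two adversarial features matter for testing. *Homolog confusers* force
normalization to use document context: the name index ranks one variant
first, but only the article's variant appears in its document index.
*Lexicon-only genes* have ordinary lowercase names ("sharpin", "lumen") and
occur only in test-split articles, so the tagger has never seen them and
their shape carries no signal; cue-ambiguous filler sentences (the same
lexical cues with ordinary nouns in the gene slots) prevent the tagger from
tagging by context alone. These genes are recoverable only through the
lexicon scan, which is what makes the lexicon-ablation recall drop a
well-posed check.

The accompanying knowledge bundle is oracle-consistent — every gold mention's
ID is reachable via the name index and at least one document index — so
normalization recovers 100% of gold IDs on the undegraded bundle.
`corrupt_knowledge` removes primary document-index entries independently at a
given rate to exercise the fallback path.

What the generator does **not** emulate: real PubMed syntax and vocabulary
breadth, nested or discontinuous mentions, abbreviation definitions,
species-prefix conventions, incomplete gold annotation (mentions outside
relations), and realistic name-candidate ambiguity beyond the confuser
mechanism. Consequently, passing fixtures demonstrates that the machinery is
implemented correctly and can learn cue-separable signal at small scale — not
that full-scale corpus performance is reproduced.

## Problem sizes and reduced configurations

Tests and the acceptance script use reduced models chosen so the whole suite
trains on one CPU in minutes: the tagger with 16-dim character embeddings,
κ = 20 filters, 32-dim word and 8-dim word-type embeddings and π = 50 LSTM
units; the classifier with 32 filters per window and 50-dim embeddings; 3
ensemble members instead of 10. The tagger memorization check uses a
20-sentence fixture and 500 iterations; classifier recovery uses a
200-article corpus (train+dev for training, test held out) and 10 epochs; the
end-to-end run uses 100 articles with 400 tagger iterations. Stochastic
checks run three seeds and require a majority to pass.

## Numerical choices

- float64 throughout; softmax subtracts the row max before exponentiation;
  the fused cross-entropy never materializes log 0.
- `sequence_loss` treats 0·log 0 as 0 so perfect one-hot predictions score
  exactly 0.
- Max-pooling over variable-length inputs masks invalid window positions with
  −1e9 before the max; gradients flow to the first argmax.
- Words shorter than the convolution window are padded with a reserved
  (learned) PAD character to length 3; the classifier's PAD token embedding
  row is instead frozen at zero (it realizes the "zero-vector padding").
- Out-of-vocabulary words map to a trained UNK row; the character vocabulary
  is printable ASCII plus training characters.
- Prediction ties in the fallback rule break on the lexicographically
  smallest canonical pair; all other tie-breaks (argmax) take the first
  maximum.
- Seeds: ensemble member seeds are drawn from a master generator
  (`default_rng(master_seed).integers(0, 2**31 - 1)`), so any master seed
  reproduces the full ensemble bit-for-bit.

## Known limitations

- The neural core is a minimal educational-grade autodiff; it is fast enough
  for the reduced configurations but not tuned for full-scale training (no
  BLAS-level fusion, no GPU).
- The tokenizer and sentence splitter are rule-based and configurable in
  principle but not pluggable via config files; any change alters
  sentence-example counts.
- Normalization has no species disambiguation beyond the document-set
  restriction, and deliberately no fuzzy string matching (it performed poorly
  when evaluated as an alternative).
- The live E-utilities adapter is provided for completeness but untested
  against the real service inside this repository's test suite (tests are
  fully offline by design).
- Mention-level NER scoring against an official challenge scorer and
  confidence-interval resampling protocols are documented concepts but not
  implemented deliverables.
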