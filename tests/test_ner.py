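"""The CNN-LSTM tagger: feature functions, forward-pass pieces, training
contracts, ensembling and the lexicon post-processor."""

import math

import numpy as np
import pytest

from conftest import REDUCED_NER_MODEL, make_document
from ppimx.corpus import GeneMention, Provenance
from ppimx.ner import (
    NerEnsemble,
    NerModel,
    NerModelConfig,
    NerTrainConfig,
    TrainedNer,
    build_vocabs,
    char_type,
    examples_from_corpus,
    lexicon_scan,
    sequence_loss,
    span_f1,
    tag_document,
    train_ner,
    train_ner_ensemble,
    word_type,
)
from ppimx.nn import autodiff as ad


class TestCharAndWordTypes:
    @pytest.mark.parametrize(
        "c,expected",
        [("a", "lowercase"), ("A", "uppercase"), ("3", "other"),
         ("-", "punctuation"), (" ", "other"), ("+", "punctuation")],
    )
    def test_char_type(self, c, expected):
        assert char_type(c) == expected

    def test_char_type_rejects_strings(self):
        with pytest.raises(ValueError):
            char_type("ab")

    @pytest.mark.parametrize(
        "w,expected",
        [("shank", "all_lower"), ("Shank", "cap_first"), ("SHANK", "all_upper"),
         ("Shank3", "cap_first"), ("mRNA", "mixed"), ("123", "other"),
         ("abc-1", "all_lower")],
    )
    def test_word_type(self, w, expected):
        assert word_type(w) == expected

    def test_word_type_rejects_empty(self):
        with pytest.raises(ValueError):
            word_type("")


def _small_model(**over):
    cfg_kw = dict(char_emb_dim=2, char_type_emb_dim=3, char_filters=1,
                  word_emb_dim=4, word_type_emb_dim=2, lstm_hidden=3)
    cfg_kw.update(over)
    cfg = NerModelConfig(**cfg_kw)
    vocabs = build_vocabs([(["abc", "Ab", "xy"], ["O", "O", "O"])])
    return NerModel(cfg, *vocabs, seed=0)


class TestTokenDistribution:
    def test_equal_logits_give_uniform(self):
        m = _small_model()
        m.out.W.data[:] = 0.0
        m.out.b.data[:] = 0.0
        p = m.token_distribution(np.ones(6))
        assert p == pytest.approx([1 / 3] * 3)

    def test_logits_one_two_three(self):
        m = _small_model()
        m.out.W.data[:] = 0.0
        m.out.b.data = np.array([1.0, 2.0, 3.0])
        p = m.token_distribution(np.zeros(6))
        assert p == pytest.approx([0.09003057, 0.24472847, 0.66524096], abs=1e-6)

    def test_sums_to_one_and_positive_for_random_logits(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = ad.softmax(rng.normal(scale=10, size=3))
            assert abs(p.sum() - 1.0) < 1e-9 and (p > 0).all()


class TestSequenceLoss:
    def test_perfect_predictions_loss_zero(self):
        y = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0])]
        assert sequence_loss(y, y) == pytest.approx(0.0)

    def test_uniform_predictions_loss_ln3(self):
        p = [np.full(3, 1 / 3)] * 5
        y = [np.eye(3)[i % 3] for i in range(5)]
        assert sequence_loss(p, y) == pytest.approx(math.log(3))

    def test_hand_computed_two_token_case(self):
        p = [np.array([0.5, 0.25, 0.25]), np.array([0.1, 0.8, 0.1])]
        y = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0])]
        assert sequence_loss(p, y) == pytest.approx(0.45814536593707755)

    def test_training_loss_agrees_with_formula(self):
        """Dual route: the fused training loss equals the per-sequence mean
        cross-entropy computed from the predicted distributions."""
        m = _small_model()
        batch = [(["abc", "xy"], ["I-GENE", "O"]), (["Ab"], ["O"])]
        fused = float(m.loss(batch).data)
        total = 0.0
        for toks, labs in batch:
            probs = list(m.predict_probs(toks))
            onehots = [np.eye(3)[{"B-GENE": 0, "I-GENE": 1, "O": 2}[l]] for l in labs]
            total += sequence_loss(probs, onehots)
        assert fused == pytest.approx(total / len(batch), abs=1e-9)


class TestCharCnn:
    def test_zero_filters_give_zero_vector(self):
        m = _small_model()
        m.W_char.data[:] = 0.0
        m.b_char.data[:] = 0.0
        assert m.encode_word_chars("abc") == pytest.approx(np.zeros(1))

    def test_hand_computed_three_char_word_single_filter(self):
        m = _small_model()
        rng = np.random.default_rng(42)
        m.W_char.data = rng.normal(size=m.W_char.data.shape)
        m.b_char.data = np.array([0.3])
        u = m.encode_word_chars("abc")
        # independent computation with explicit loops
        rows = []
        for c in "abc":
            ce = m.char_emb.table.data[m.char_vocab[c]]
            te = m.ctype_emb.table.data[0]  # lowercase
            rows.append(np.concatenate([ce, te]))
        window = np.concatenate(rows)  # single window of a 3-char word
        expected = max(0.0, float(np.sum(window * m.W_char.data[:, 0]) + 0.3))
        assert u[0] == pytest.approx(expected, abs=1e-9)
        # a 3-char word has exactly one window, so u is that single value
        assert u.shape == (1,)

    def test_short_words_are_padded(self):
        m = _small_model()
        assert m.encode_word_chars("a").shape == (1,)

    def test_case_carried_by_type_embeddings_only(self):
        m = _small_model()
        # same lowercased characters, same types row would differ:
        u_lower = m.encode_word_chars("abc")
        m.ctype_emb.table.data[:] = 0.0  # collapse type information
        u_ab = m.encode_word_chars("ABC")
        u_ab2 = m.encode_word_chars("abc")
        assert u_ab == pytest.approx(u_ab2)
        del u_lower


class TestEncodeSequence:
    def test_context_vector_has_length_2pi(self):
        m = _small_model(lstm_hidden=200)
        h = m.encode_sequence(["abc"])
        assert h.shape == (1, 400)

    def test_zero_weights_give_zero_context(self):
        m = _small_model()
        zeros = {k: np.zeros_like(v) for k, v in m.get_weights().items()}
        m.set_weights(zeros)
        h = m.encode_sequence(["abc", "xy"])
        assert h == pytest.approx(np.zeros((2, 6)))

    def test_reversal_swaps_forward_and_backward_components(self):
        m = _small_model()
        # share parameters between the two directions
        m.lstm_b.W.data = m.lstm_f.W.data.copy()
        m.lstm_b.U.data = m.lstm_f.U.data.copy()
        m.lstm_b.b.data = m.lstm_f.b.data.copy()
        toks = ["abc", "xy", "Ab"]
        h = m.encode_sequence(toks)
        r = m.encode_sequence(list(reversed(toks)))
        H = m.cfg.lstm_hidden
        for i in range(len(toks)):
            assert h[i, :H] == pytest.approx(r[len(toks) - 1 - i, H:])
            assert h[i, H:] == pytest.approx(r[len(toks) - 1 - i, :H])


def _fixture_examples(tiny_bundle, n=20):
    ex = examples_from_corpus(tiny_bundle.train) + examples_from_corpus(tiny_bundle.dev)
    return [e for e in ex if e[0]][:n]


FAST_TRAIN = NerTrainConfig(max_iterations=60, checkpoint_every=30,
                            batch_size=10, early_stop_patience=2)


class TestTraining:
    def test_same_seed_gives_identical_predictions(self, tiny_bundle):
        ex = _fixture_examples(tiny_bundle, 10)
        runs = []
        for _ in range(2):
            tr = train_ner(ex, ex, FAST_TRAIN, REDUCED_NER_MODEL, seed=5)
            runs.append([tr.model.predict_probs(t) for t, _ in ex])
        for a, b in zip(*runs):
            assert a == pytest.approx(b, abs=0)

    def test_empty_dev_set_is_an_error(self, tiny_bundle):
        ex = _fixture_examples(tiny_bundle, 4)
        with pytest.raises(ValueError):
            train_ner(ex, [], FAST_TRAIN, REDUCED_NER_MODEL, seed=0)

    def test_flat_dev_f1_stops_after_patience_checkpoints(self):
        # all-O data: no spans, so dev span F1 is identically zero
        ex = [([f"w{i}", "x"], ["O", "O"]) for i in range(6)]
        cfg = NerTrainConfig(max_iterations=10_000, checkpoint_every=10,
                             batch_size=4, early_stop_patience=3)
        tr = train_ner(ex, ex, cfg, REDUCED_NER_MODEL, seed=1)
        # improvement at checkpoint 1 (from -inf), then 3 flat checkpoints
        assert tr.history[-1][0] == (1 + cfg.early_stop_patience) * cfg.checkpoint_every


class TestEnsemble:
    def test_subset_fraction_one_leaves_no_dev_and_errors(self, tiny_bundle):
        ex = _fixture_examples(tiny_bundle, 6)
        cfg = NerTrainConfig(max_iterations=30, checkpoint_every=30,
                             ensemble_size=1, subset_fraction=1.0)
        with pytest.raises(ValueError):
            train_ner_ensemble(ex, cfg, REDUCED_NER_MODEL, master_seed=0)

    def test_members_have_distinct_seeds_and_weights(self, tiny_bundle):
        ex = _fixture_examples(tiny_bundle, 10)
        cfg = NerTrainConfig(max_iterations=30, checkpoint_every=30,
                             ensemble_size=2, early_stop_patience=1)
        ens = train_ner_ensemble(ex, cfg, REDUCED_NER_MODEL, master_seed=3)
        a, b = ens.members
        assert a.seed != b.seed
        assert not np.allclose(a.model.get_weights()["out_W"],
                               b.model.get_weights()["out_W"])

    def test_ensemble_reproducible_under_master_seed(self, tiny_bundle):
        ex = _fixture_examples(tiny_bundle, 10)
        cfg = NerTrainConfig(max_iterations=30, checkpoint_every=30,
                             ensemble_size=2, early_stop_patience=1)
        e1 = train_ner_ensemble(ex, cfg, REDUCED_NER_MODEL, master_seed=3)
        e2 = train_ner_ensemble(ex, cfg, REDUCED_NER_MODEL, master_seed=3)
        toks = ex[0][0]
        assert e1.predict_probs(toks) == pytest.approx(e2.predict_probs(toks), abs=0)

    def test_save_load_roundtrip(self, tiny_bundle, tmp_path):
        ex = _fixture_examples(tiny_bundle, 8)
        cfg = NerTrainConfig(max_iterations=30, checkpoint_every=30,
                             ensemble_size=1, early_stop_patience=1)
        ens = train_ner_ensemble(ex, cfg, REDUCED_NER_MODEL, master_seed=0)
        ens.save(str(tmp_path))
        again = NerEnsemble.load(str(tmp_path))
        toks = ex[0][0]
        assert again.predict_probs(toks) == pytest.approx(ens.predict_probs(toks))


class _StubModel:
    def __init__(self, rows):
        self.rows = rows  # token -> prob row

    def predict_probs(self, tokens):
        return np.array([self.rows[t] for t in tokens])


def _stub_ensemble(row_maps):
    members = [TrainedNer(_StubModel(r), 0, 0.0, 0) for r in row_maps]
    return NerEnsemble(members, NerModelConfig(), {}, {})


class TestTagDocument:
    def test_probability_averaging_decides(self):
        # tags ordered (B-GENE, I-GENE, O): member probs avg to I-GENE
        m1 = {"Xbp7": [0.0, 0.6, 0.4]}
        m2 = {"Xbp7": [0.0, 0.2, 0.8]}
        doc = make_document("1", "Xbp7")
        ens = _stub_ensemble([m1, m2])
        # averaged: (0.0, 0.4, 0.6) -> O wins -> no mention
        assert tag_document(ens, doc) == []
        m2b = {"Xbp7": [0.0, 0.8, 0.2]}
        ens2 = _stub_ensemble([m1, m2b])
        assert [m.text for m in tag_document(ens2, doc)] == ["Xbp7"]

    def test_agreeing_members_match_single_member(self):
        rows = {"Xbp7": [0.1, 0.7, 0.2], "binds": [0.0, 0.1, 0.9]}
        doc = make_document("1", "Xbp7 binds")
        one = tag_document(_stub_ensemble([rows]), doc)
        three = tag_document(_stub_ensemble([rows] * 3), doc)
        assert one == three

    def test_matches_average_then_decode_oracle(self, tiny_bundle, mini_pipeline):
        _, ner_ens, _ = mini_pipeline
        from ppimx.augment import repair_iob
        from ppimx.corpus import LabeledSequence, decode_iob
        from ppimx.ner import TAGS

        doc = tiny_bundle.test.documents[0]
        got = tag_document(ner_ens, doc)
        expected = []
        for sent in doc.tokens:
            toks = [doc.token_text(t) for t in sent]
            avg = np.mean([m.model.predict_probs(toks) for m in ner_ens.members], axis=0)
            labels = repair_iob([TAGS[k] for k in avg.argmax(axis=1)])
            expected.extend(decode_iob(LabeledSequence(list(sent), labels), doc))
        assert got == expected

    def test_empty_document_gives_empty_list(self, mini_pipeline):
        _, ner_ens, _ = mini_pipeline
        doc = make_document("1", "", "")
        assert tag_document(ner_ens, doc) == []


def _bruteforce_lexicon(document, lexicon, existing):
    """Oracle: enumerate every token-aligned substring, keep lexicon matches,
    sort by (length desc, start asc), greedily accept non-overlapping."""
    toks = document.all_tokens()
    lower_names = {n.lower() for n in lexicon}
    cands = set()
    for i in range(len(toks)):
        for j in range(i, len(toks)):
            s, e = toks[i][0], toks[j][1]
            if document.full_text[s:e].lower() in lower_names:
                cands.add((s, e))
    taken = [(m.start, m.end) for m in existing]
    out = []
    for s, e in sorted(cands, key=lambda se: (-(se[1] - se[0]), se[0], se[1])):
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        out.append((s, e))
    return sorted(out)


class TestLexiconScan:
    def test_adds_unseen_lexicon_gene(self):
        doc = make_document("1", "Only Sharpin is mentioned here")
        ms = lexicon_scan(doc, {"Sharpin": ["81858"]}, [])
        assert [m.text for m in ms] == ["Sharpin"]
        assert ms[0].provenance == Provenance.LEXICON

    def test_longer_mentions_prioritized(self):
        doc = make_document("1", "Shank3 binds stuff")
        ms = lexicon_scan(doc, {"Shank": ["1"], "Shank3": ["2"]}, [])
        assert [m.text for m in ms] == ["Shank3"]

    def test_overlap_with_existing_span_is_skipped(self):
        doc = make_document("1", "Shank3 binds stuff")
        existing = [GeneMention(0, 6, "Shank3", Provenance.MODEL)]
        assert lexicon_scan(doc, {"Shank3": ["2"]}, existing) == []

    def test_case_insensitive_token_anchored(self):
        doc = make_document("1", "SHARPIN and sharpinol")
        ms = lexicon_scan(doc, {"Sharpin": ["8"]}, [])
        # "sharpinol" has no token boundary after "sharpin"
        assert [(m.start, m.end) for m in ms] == [(0, 7)]

    def test_matches_bruteforce_oracle_on_random_draws(self):
        rng = np.random.default_rng(13)
        vocab = ["Xbp7", "TRK9", "abc", "binds", "the", "kinase", "of", "p53"]
        for _ in range(200):
            n = int(rng.integers(3, 12))
            words = [vocab[rng.integers(len(vocab))] for _ in range(n)]
            doc = make_document("1", " ".join(words))
            lex_names = {vocab[i] for i in rng.integers(0, len(vocab), size=3)}
            lexicon = {n2: ["g"] for n2 in lex_names}
            toks = doc.all_tokens()
            existing = []
            if rng.random() < 0.5 and toks:
                a = int(rng.integers(0, len(toks)))
                s, e = toks[a][0], toks[a][1]
                existing = [GeneMention(s, e, doc.full_text[s:e], Provenance.MODEL)]
            got = [(m.start, m.end) for m in lexicon_scan(doc, lexicon, existing)]
            assert sorted(got) == _bruteforce_lexicon(doc, lexicon, existing)


class TestSpanF1:
    def test_perfect_and_disjoint(self):
        gold = [["I-GENE", "O"], ["O", "I-GENE"]]
        assert span_f1(gold, gold) == 1.0
        assert span_f1([["O", "O"], ["O", "O"]], gold) == 0.0
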