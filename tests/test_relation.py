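"""Entity-blinded instance generation, the multi-window CNN forward pass,
training contracts and pair scoring/prediction."""

from types import SimpleNamespace

import numpy as np
import pytest

from conftest import REDUCED_RC_MODEL, instances_of, make_document
from ppimx.corpus import GeneMention
from ppimx.relation import (
    GENE_A,
    GENE_B,
    GENE_N,
    GENE_S,
    RcEnsemble,
    RcInstance,
    RcModel,
    RcModelConfig,
    RcTrainConfig,
    build_rc_vocab,
    generate_instances,
    pair_scores,
    predict_pairs,
    rc_forward,
    score_pair,
    train_rc,
    train_rc_ensemble,
)


def _doc_with_genes(names_ids):
    text = " ".join(n for n, _ in names_ids) + " interact strongly ."
    doc = make_document("1", "A study .", text)
    mentions = []
    pos = len(doc.title) + 1
    for name, gid in names_ids:
        mentions.append(GeneMention(pos, pos + len(name), name, gene_id=gid))
        pos += len(name) + 1
    for m in mentions:
        m.validate(doc)
    return doc, mentions


class TestGenerateInstances:
    @pytest.mark.parametrize("g", [1, 2, 3, 4, 5, 6])
    def test_instance_count_is_g_squared(self, g):
        doc, mentions = _doc_with_genes([(f"GN{i}", f"id{i}") for i in range(g)])
        instances = generate_instances(doc, mentions)
        assert len(instances) == g * g
        assert sum(1 for i in instances if i.is_self) == g

    def test_single_candidate_uses_gene_s(self):
        doc, mentions = _doc_with_genes([("Xbp7", "10")])
        (inst,) = generate_instances(doc, mentions)
        assert GENE_S in inst.tokens() and "Xbp7" not in inst.tokens()

    def test_third_gene_becomes_gene_n(self):
        doc, mentions = _doc_with_genes([("Ga", "1"), ("Gb", "2"), ("Gc", "3")])
        inst = next(
            i for i in generate_instances(doc, mentions)
            if (i.first_id, i.second_id) == ("1", "2")
        )
        toks = inst.tokens()
        assert GENE_A in toks and GENE_B in toks and GENE_N in toks

    def test_no_candidate_surface_strings_leak(self, bundle):
        for doc in bundle.train.documents[:10]:
            mentions = bundle.train.mentions[doc.pmid]
            names = {m.text for m in mentions}
            for inst in generate_instances(doc, mentions):
                leaked = names & set(inst.tokens())
                assert not leaked

    def test_labels_are_order_insensitive(self):
        doc, mentions = _doc_with_genes([("Ga", "1"), ("Gb", "2")])
        instances = generate_instances(doc, mentions, gold_pairs={("2", "1")})
        by_order = {(i.first_id, i.second_id): i.label for i in instances}
        assert by_order[("1", "2")] is True and by_order[("2", "1")] is True
        assert by_order[("1", "1")] is False

    def test_no_candidates_gives_empty_list(self):
        doc = make_document("1", "nothing")
        assert generate_instances(doc, []) == []

    def test_truncation_never_cuts_first_bound_token(self):
        doc, mentions = _doc_with_genes([("Ga", "1"), ("Gb", "2")])
        instances = generate_instances(doc, mentions, max_tokens=1)
        for inst in instances:
            toks = inst.tokens()
            if inst.is_self:
                assert GENE_S in toks
            else:
                assert GENE_A in toks and GENE_B in toks


SMALL_RC = RcModelConfig(filters=1, word_emb_dim=2, dropout=0.0)


def _inst(tokens, first="A", second="B", pmid="1"):
    return RcInstance(pmid, first, second, [list(tokens)])


class TestForwardPass:
    def test_zero_weights_give_half(self):
        vocab = build_rc_vocab([_inst(["x", "y"])])
        m = RcModel(SMALL_RC, vocab, seed=0)
        zeros = {k: np.zeros_like(v) for k, v in m.get_weights().items()}
        m.set_weights(zeros)
        assert rc_forward(_inst(["x", "y"]), m) == pytest.approx(0.5)

    def test_padded_length_and_feature_map_lengths(self):
        vocab = build_rc_vocab([_inst(["x"])])
        m = RcModel(SMALL_RC, vocab, seed=0)
        idx = m._indices(_inst(["x"]))
        assert len(idx) == 9  # 4 pads + 1 token + 4 pads
        assert [len(idx) - w + 1 for w in m.cfg.window_sizes] == [7, 6, 5]

    def test_inter_sentence_padding(self):
        vocab = build_rc_vocab([_inst(["x"])])
        m = RcModel(SMALL_RC, vocab, seed=0)
        inst = RcInstance("1", "A", "B", [["x"], ["y"]])
        assert len(m._indices(inst)) == 4 + 1 + 4 + 1 + 4

    def test_hand_computed_two_token_forward(self):
        vocab = build_rc_vocab([_inst(["x", "y"])])
        m = RcModel(SMALL_RC, vocab, seed=3)
        inst = _inst(["x", "y"])
        # independent computation with explicit loops
        idx = [0] * 4 + [vocab["x"], vocab["y"]] + [0] * 4
        E = m.emb.table.data
        seq = np.stack([E[i] for i in idx])  # (10, 2)
        pooled = []
        for w, W, b in zip(m.cfg.window_sizes, m.conv_W, m.conv_b):
            vals = []
            for j in range(len(idx) - w + 1):
                window = seq[j : j + w].reshape(-1)
                vals.append(max(0.0, float(window @ W.data[:, 0] + b.data[0])))
            pooled.append(max(vals))
        logits = np.array(pooled) @ m.out.W.data + m.out.b.data
        z = logits - logits.max()
        expected = float(np.exp(z[1]) / np.exp(z).sum())
        assert rc_forward(inst, m) == pytest.approx(expected, abs=1e-9)


class TestScoring:
    def _random_ensemble(self, instances, n=2):
        vocab = build_rc_vocab(instances)
        members = [
            SimpleNamespace(model=RcModel(REDUCED_RC_MODEL, vocab, seed=s))
            for s in (1, 2)[:n]
        ]
        return SimpleNamespace(members=members)

    def test_score_is_symmetric_in_pair_order(self):
        doc, mentions = _doc_with_genes([("Ga", "1"), ("Gb", "2"), ("Gc", "3")])
        instances = generate_instances(doc, mentions)
        ens = self._random_ensemble(instances)
        assert score_pair(ens, instances, ("1", "2")) == pytest.approx(
            score_pair(ens, instances, ("2", "1"))
        )

    def test_score_equals_bruteforce_mean_over_members_and_orders(self):
        doc, mentions = _doc_with_genes([("Ga", "1"), ("Gb", "2")])
        instances = generate_instances(doc, mentions)
        ens = self._random_ensemble(instances, n=2)
        probs = []
        for member in ens.members:
            for inst in instances:
                if inst.pair == ("1", "2"):
                    probs.append(rc_forward(inst, member.model))
        assert score_pair(ens, instances, ("1", "2")) == pytest.approx(np.mean(probs))

    def test_unknown_pair_raises(self):
        doc, mentions = _doc_with_genes([("Ga", "1")])
        instances = generate_instances(doc, mentions)
        ens = self._random_ensemble(instances)
        with pytest.raises(KeyError):
            score_pair(ens, instances, ("1", "9"))

    def test_member_and_order_average_arithmetic(self):
        class Fixed:
            def __init__(self, table):
                self.table = table

            def predict_proba(self, instances):
                return np.array([self.table[(i.first_id, i.second_id)] for i in instances])

        insts = [_inst(["x"], "A", "B"), _inst(["x"], "B", "A")]
        m = Fixed({("A", "B"): 0.6, ("B", "A"): 0.5})
        ens = SimpleNamespace(members=[SimpleNamespace(model=m)])
        assert score_pair(ens, insts, ("A", "B")) == pytest.approx(0.55)


class _FixedEnsemble:
    """Stub ensemble whose single member scores instances from a pair table."""

    def __init__(self, table):
        model = SimpleNamespace(
            predict_proba=lambda insts: np.array(
                [table[i.pair] for i in insts]
            )
        )
        self.members = [SimpleNamespace(model=model)]


def _pair_instances(pairs):
    out = []
    for a, b in pairs:
        if a == b:
            out.append(_inst([GENE_S], a, b))
        else:
            out.append(_inst([GENE_A, GENE_B], a, b))
            out.append(_inst([GENE_B, GENE_A], b, a))
    return out


class TestPredictPairs:
    def test_threshold_rule(self):
        insts = _pair_instances([("A", "B"), ("A", "C")])
        ens = _FixedEnsemble({("A", "B"): 0.7, ("A", "C"): 0.2})
        assert predict_pairs(ens, insts) == {("A", "B")}

    def test_fallback_picks_best_below_threshold(self):
        insts = _pair_instances([("A", "B"), ("A", "C")])
        ens = _FixedEnsemble({("A", "B"): 0.4, ("A", "C"): 0.3})
        assert predict_pairs(ens, insts) == {("A", "B")}

    def test_exactly_half_is_not_positive(self):
        insts = _pair_instances([("A", "B"), ("A", "C")])
        ens = _FixedEnsemble({("A", "B"): 0.5, ("A", "C"): 0.6})
        assert predict_pairs(ens, insts) == {("A", "C")}

    def test_fallback_tie_breaks_lexicographically(self):
        insts = _pair_instances([("A", "B"), ("A", "C")])
        ens = _FixedEnsemble({("A", "B"): 0.3, ("A", "C"): 0.3})
        assert predict_pairs(ens, insts) == {("A", "B")}

    def test_no_candidates_gives_empty_set(self):
        ens = _FixedEnsemble({})
        assert predict_pairs(ens, []) == set()

    def test_at_least_one_pair_when_candidates_exist(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            pairs = [("A", "B"), ("B", "C"), ("C", "C")]
            table = {tuple(sorted(p)): float(rng.random() * 0.5) for p in pairs}
            ens = _FixedEnsemble(table)
            assert len(predict_pairs(ens, _pair_instances(pairs))) >= 1


FAST_RC_TRAIN = RcTrainConfig(epochs=2, ensemble_size=2)


class TestTraining:
    def test_same_seed_gives_identical_history(self, tiny_bundle):
        instances = instances_of(tiny_bundle.train)
        a = train_rc(instances, FAST_RC_TRAIN, REDUCED_RC_MODEL, seed=4)
        b = train_rc(instances, FAST_RC_TRAIN, REDUCED_RC_MODEL, seed=4)
        assert a.history == b.history
        assert a.model.get_weights()["out_W"] == pytest.approx(
            b.model.get_weights()["out_W"], abs=0
        )

    def test_single_class_training_set_is_an_error(self):
        insts = [_inst([GENE_A, GENE_B], pmid=str(i)) for i in range(10)]
        for i in insts:
            i.label = True
        with pytest.raises(ValueError):
            train_rc(insts, FAST_RC_TRAIN, REDUCED_RC_MODEL, seed=0)

    def test_unlabeled_instances_are_an_error(self, tiny_bundle):
        instances = instances_of(tiny_bundle.train)
        instances[0].label = None
        with pytest.raises(ValueError):
            train_rc(instances, FAST_RC_TRAIN, REDUCED_RC_MODEL, seed=0)

    def test_member_splits_differ_under_distinct_seeds(self, tiny_bundle):
        instances = instances_of(tiny_bundle.train)
        ens = train_rc_ensemble(instances, FAST_RC_TRAIN, REDUCED_RC_MODEL, master_seed=6)
        a, b = ens.members
        assert a.seed != b.seed
        assert not np.allclose(a.model.get_weights()["out_W"],
                               b.model.get_weights()["out_W"])

    def test_save_load_roundtrip(self, tiny_bundle, tmp_path):
        instances = instances_of(tiny_bundle.train)
        ens = train_rc_ensemble(instances, FAST_RC_TRAIN, REDUCED_RC_MODEL, master_seed=6)
        ens.save(str(tmp_path))
        again = RcEnsemble.load(str(tmp_path))
        probs_a = ens.members[0].model.predict_proba(instances[:5])
        probs_b = again.members[0].model.predict_proba(instances[:5])
        assert probs_a == pytest.approx(probs_b)
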