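import numpy as np
import pytest

from ppimx.corpus import Document, segment
from ppimx.fixtures import FixtureConfig, generate_fixture_bundle
from ppimx.ner import (
    NerModelConfig,
    NerTrainConfig,
    examples_from_corpus,
    train_ner_ensemble,
)
from ppimx.relation import (
    RcModelConfig,
    RcTrainConfig,
    generate_instances,
    train_rc_ensemble,
)

# Reduced architecture used throughout the tests so CPU training stays fast;
# kappa/pi follow the reduced tagger configuration, the remaining dimensions
# are scaled proportionally.
REDUCED_NER_MODEL = NerModelConfig(
    char_emb_dim=16, char_filters=20, word_emb_dim=32,
    word_type_emb_dim=8, lstm_hidden=50,
)
REDUCED_RC_MODEL = RcModelConfig(filters=32, word_emb_dim=50)


def make_document(pmid: str, title: str, abstract: str = "") -> Document:
    return segment(Document(pmid=pmid, title=title, abstract=abstract))


def instances_of(corpus):
    out = []
    for doc in corpus.documents:
        out.extend(
            generate_instances(doc, corpus.mentions[doc.pmid], corpus.pairs[doc.pmid])
        )
    return out


@pytest.fixture(scope="session")
def bundle():
    """Standard fixture bundle at the generator's default study conditions."""
    return generate_fixture_bundle(FixtureConfig(n_articles=100, seed=21))


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_fixture_bundle(FixtureConfig(n_articles=12, seed=3))


@pytest.fixture(scope="session")
def mini_pipeline():
    """Small trained NER + RC ensembles on a 40-article bundle, shared by the
    pipeline-level tests (training happens once per session)."""
    b = generate_fixture_bundle(FixtureConfig(n_articles=40, seed=9))
    ner_tc = NerTrainConfig(
        max_iterations=300, checkpoint_every=50, ensemble_size=2, early_stop_patience=4
    )
    ner_ens = train_ner_ensemble(examples_from_corpus(b.train), ner_tc,
                                 REDUCED_NER_MODEL, master_seed=1)
    rc_tc = RcTrainConfig(epochs=8, ensemble_size=2)
    rc_ens = train_rc_ensemble(instances_of(b.train), rc_tc, REDUCED_RC_MODEL,
                               master_seed=2)
    return b, ner_ens, rc_ens
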