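"""Shared fixtures: synthetic corpora, the demo ruleset, trained models.

Training fixtures are session-scoped so the recurrent models are fit once
and reused by the classifier, ensemble, and end-to-end tests.  All seeds
are fixed; the suite is fully deterministic.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List

import pytest
from hypothesis import settings

import asdphen as ap
from asdphen.classifiers import PRESETS, HashEmbeddings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


CORPUS_SEED = 11
TRAIN_SEED = 5
EMB_DIM = 32
N_TRAIN_RECORDS = 48


@pytest.fixture(scope="session")
def demo_rs():
    return ap.demo_ruleset()


@pytest.fixture(scope="session")
def small_corpus() -> List[ap.Record]:
    """Desk-scale corpus with the default annotation noise / cross-talk."""
    return ap.generate_corpus(ap.small_config(seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def corpus_split(small_corpus):
    return small_corpus[:N_TRAIN_RECORDS], small_corpus[N_TRAIN_RECORDS:]


@pytest.fixture(scope="session")
def hash_emb() -> HashEmbeddings:
    return HashEmbeddings(dimension=EMB_DIM, seed=0)


@pytest.fixture(scope="session")
def binary_family(corpus_split, hash_emb):
    train, _ = corpus_split
    cfg = PRESETS["binary_gru_small"].with_seed(TRAIN_SEED)
    return ap.train_binary_per_criterion(train, cfg, hash_emb)


@pytest.fixture(scope="session")
def hybrid_family(corpus_split, hash_emb, demo_rs):
    train, _ = corpus_split
    cfg = PRESETS["hybrid_lstm_small"].with_seed(TRAIN_SEED)
    return ap.train_hybrid(train, cfg, hash_emb, demo_rs)


@pytest.fixture(scope="session")
def multilabel_model(corpus_split, hash_emb):
    train, _ = corpus_split
    cfg = PRESETS["multilabel_lstm_small"].with_seed(TRAIN_SEED)
    return ap.train_multilabel(train, cfg, hash_emb)


@pytest.fixture(scope="session")
def test_predictions(corpus_split, demo_rs, binary_family, hybrid_family,
                     multilabel_model) -> Dict[str, ap.PredictionSet]:
    """All four predictors applied to the held-out split, keyed by role."""
    _, test = corpus_split
    return {
        "parser": ap.parse_corpus(test, demo_rs),
        "binary_gru": ap.predict(binary_family, test),
        "hybrid_lstm": ap.predict(hybrid_family, test),
        "multilabel_lstm": ap.predict(multilabel_model, test),
    }


@pytest.fixture(scope="session")
def clean_corpus() -> List[ap.Record]:
    """Noise-free corpus: every cue sentence carries its gold label."""
    cfg = dataclasses.replace(ap.small_config(seed=CORPUS_SEED + 1),
                              cue_noise=0.0, cross_talk=0.0)
    return ap.generate_corpus(cfg)


@pytest.fixture(scope="session")
def clean_family(clean_corpus, hash_emb):
    cfg = PRESETS["binary_gru_small"].with_seed(TRAIN_SEED)
    return ap.train_binary_per_criterion(clean_corpus[:N_TRAIN_RECORDS], cfg, hash_emb)
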