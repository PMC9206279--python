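from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gquadfold import (
    CorpusSpec,
    MockEngine,
    ViennaRNAEngine,
    build_training_table,
    generate_corpus,
    train_classifier,
    train_regressor,
)
from gquadfold.predictor import _annotate_motif

#: The unequal-stem example: second G-run has five guanines, the others three.
WORKED_EXAMPLE = "GGGtttttttGGGGGtttttttGGGtttGGG"


@pytest.fixture(scope="session")
def engine():
    return ViennaRNAEngine()


@pytest.fixture(scope="session")
def mock_engine():
    return MockEngine()


def _labeled_corpus(engine, n: int, seed: int):
    spec = CorpusSpec(n_sequences=n, seed=seed, negative_fraction=0.35)
    records, truth = generate_corpus(spec)
    motifs, queries = [], {}
    for rid, seq in records:
        motif = _annotate_motif(rid, seq)
        if motif is not None:
            motifs.append(motif)
            queries[rid] = seq
    table = build_training_table(motifs, engine, query_seqs=queries)
    return records, truth, table


@pytest.fixture(scope="session")
def small_corpus(engine):
    """1,200 records, engine-labeled: shared by model and predictor tests."""
    return _labeled_corpus(engine, n=1200, seed=20230)


@pytest.fixture(scope="session")
def labeled_table(small_corpus):
    return small_corpus[2]


@pytest.fixture(scope="session")
def classifier_bundle(labeled_table):
    return train_classifier(labeled_table, "xgboost", seed=5)


@pytest.fixture(scope="session")
def regressor_bundle(labeled_table):
    return train_regressor(labeled_table, "xgboost", seed=5)
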