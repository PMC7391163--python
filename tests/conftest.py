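"""Shared fixtures: tiny hand-built models and small generated corpora."""

from __future__ import annotations

import numpy as np
import pytest

from embaudit import GeneratorConfig, deidentify, generate_corpus
from embaudit.embeddings import EmbeddingModel


def make_model(vectors: dict[str, list[float] | np.ndarray]) -> EmbeddingModel:
    """Build an EmbeddingModel from an explicit token -> vector map."""
    index = {tok: i for i, tok in enumerate(sorted(vectors))}
    mat = np.asarray([vectors[tok] for tok in sorted(vectors)], dtype=np.float64)
    return EmbeddingModel(index=index, vectors=mat)


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_patients=30,
        name_pool_first=15,
        name_pool_last=20,
        n_diagnoses=10,
        notes_per_patient_range=(2, 3),
        note_len_range=(8, 15),
        background_vocab_size=120,
        association_prob=0.9,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_corpus(tiny_config):
    return generate_corpus(tiny_config)


@pytest.fixture(scope="session")
def tiny_deidentified(tiny_corpus):
    corpus, records, catalogue = tiny_corpus
    # records are mutated in place by deidentify; keep this fixture the
    # single source of retained flags
    deid, truth = deidentify(corpus, records, "remove", 0.5, seed=12)
    return deid, records, catalogue, truth
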