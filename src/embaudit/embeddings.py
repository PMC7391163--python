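"""Embedding training, vector arithmetic, and the two audit distance metrics.

The trainers are scikit-learn-style estimators (:class:`Word2Vec` for CBOW
and Skipgram, :class:`GloVe`) whose ``fit`` consumes an iterable of token
sequences (or a :class:`~embaudit.corpus.Corpus`) and exposes the fitted
vocabulary and vectors through trailing-underscore attributes; ``transform``
maps token sequences to mean phrase vectors, so the estimators compose with
sklearn pipelines.  :class:`EmbeddingModel` is the lightweight fitted
container every audit stage consumes, and round-trips through the word2vec
text format.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._glove import train_glove
from ._sgns import train_sgns
from .corpus import Corpus

__all__ = [
    "OOVError",
    "Hyperparams",
    "EmbeddingModel",
    "Word2Vec",
    "GloVe",
    "train_embedding",
    "vec_distance",
    "phrase_vector",
    "save_word2vec_format",
    "load_word2vec_format",
]

ALGORITHMS = ("cbow", "skipgram", "glove")
METRICS = ("cosine", "cityblock")


class OOVError(KeyError):
    """A token is missing from the embedding vocabulary."""

    def __init__(self, token: str):
        super().__init__(token)
        self.token = token

    def __str__(self) -> str:  # KeyError repr-quotes its arg
        return f"token {self.token!r} not in embedding vocabulary"


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters for one embedding model.

    ``learning_rate`` and ``epochs`` default per algorithm when ``None``
    (0.1 / 30 for skipgram, 0.2 / 30 for CBOW, 0.05 / 150 for GloVe; see the
    estimator docstrings for why these are higher than the classic
    large-corpus defaults).
    """

    algorithm: str = "skipgram"
    window: int = 5
    dim: int = 100
    learning_rate: float | None = None
    min_count: int = 1
    negative: int = 5
    glove_alpha: float = 0.75
    glove_x_max: float = 10.0
    epochs: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def _as_sentences(X) -> list[list[str]]:
    if isinstance(X, Corpus):
        return X.sentences()
    return [list(s) for s in X]


def _build_vocab(sentences: list[list[str]], min_count: int) -> tuple[dict[str, int], np.ndarray]:
    counts = Counter(tok for s in sentences for tok in s)
    items = sorted(
        ((tok, c) for tok, c in counts.items() if c >= min_count),
        key=lambda tc: (-tc[1], tc[0]),
    )
    if not items:
        raise ValueError("vocabulary is empty after min_count filtering")
    index = {tok: i for i, (tok, _c) in enumerate(items)}
    return index, np.array([c for _t, c in items], dtype=np.int64)


@dataclass
class EmbeddingModel:
    """Vocabulary -> dense-vector map plus the hyperparameters that built it."""

    index: dict[str, int]
    vectors: np.ndarray
    hyperparams: Hyperparams | None = None
    counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.index) != len(self.vectors):
            raise ValueError("index and vectors disagree in length")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vectors must be finite")

    @property
    def vocab(self) -> set[str]:
        return set(self.index)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.index[token]]
        except KeyError:
            raise OOVError(token) from None

    def phrase_vector(self, tokens: Sequence[str]) -> np.ndarray:
        return phrase_vector(self, tokens)

    def save(self, path: str | Path) -> None:
        save_word2vec_format(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        return load_word2vec_format(path)


# ---------------------------------------------------------------------------
# distances and phrase vectors


def vec_distance(u: np.ndarray, v: np.ndarray, metric: str = "cosine") -> float:
    """Cosine distance (1 - cosine similarity, in [0, 2]) or cityblock."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    if metric == "cityblock":
        return float(np.abs(u - v).sum())
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            raise ValueError("cosine distance undefined for the zero vector")
        return float(1.0 - np.dot(u, v) / (nu * nv))
    raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")


def distances_from(anchor: np.ndarray, vectors: np.ndarray, metric: str) -> np.ndarray:
    """Distances from one anchor vector to each row of ``vectors``."""
    anchor = np.asarray(anchor, dtype=np.float64)
    vectors = np.asarray(vectors, dtype=np.float64)
    if metric == "cityblock":
        return np.abs(vectors - anchor).sum(axis=1)
    if metric == "cosine":
        na = np.linalg.norm(anchor)
        nv = np.linalg.norm(vectors, axis=1)
        if na == 0.0 or np.any(nv == 0.0):
            raise ValueError("cosine distance undefined for the zero vector")
        return 1.0 - vectors @ anchor / (nv * na)
    raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")


def phrase_vector(model: EmbeddingModel, tokens: Sequence[str]) -> np.ndarray:
    """Arithmetic mean of the component token vectors.

    Used both for multi-token names and for 1-3-token diagnosis
    descriptions.  Raises :class:`OOVError` (carrying the first missing
    token) so the caller decides its own skip policy.
    """
    if len(tokens) == 0:
        raise ValueError("cannot build a phrase vector from zero tokens")
    rows = [model.vector(t) for t in tokens]
    return np.mean(np.asarray(rows, dtype=np.float64), axis=0)


# ---------------------------------------------------------------------------
# estimators


class _BaseEmbedding(TransformerMixin, BaseEstimator):
    """Shared fit/transform surface for the trainers."""

    def fit(self, X, y=None):
        sentences = _as_sentences(X)
        index, counts = _build_vocab(sentences, self.min_count)
        encoded = [
            np.array([index[t] for t in s if t in index], dtype=np.int32) for s in sentences
        ]
        encoded = [s for s in encoded if len(s) > 0]
        if not encoded:
            raise ValueError("corpus is empty after vocabulary filtering")
        self.vocabulary_ = index
        self.counts_ = counts
        self.vectors_ = self._train(encoded)
        return self

    def transform(self, X) -> np.ndarray:
        model = self.to_model()
        return np.vstack([phrase_vector(model, list(s)) for s in _as_sentences(X)])

    def get_vector(self, token: str) -> np.ndarray:
        return self.to_model().vector(token)

    def to_model(self) -> EmbeddingModel:
        if not hasattr(self, "vectors_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        return EmbeddingModel(
            index=self.vocabulary_,
            vectors=self.vectors_,
            hyperparams=self._hyperparams(),
            counts={t: int(self.counts_[i]) for t, i in self.vocabulary_.items()},
        )


class Word2Vec(_BaseEmbedding):
    """CBOW / Skipgram with negative sampling (in-repo numpy trainer).

    Deterministic for a fixed ``seed`` (single-threaded).  ``algorithm`` is
    ``"skipgram"`` or ``"cbow"``.
    """

    def __init__(
        self,
        algorithm: str = "skipgram",
        dim: int = 100,
        window: int = 5,
        min_count: int = 1,
        learning_rate: float | None = None,
        negative: int = 5,
        epochs: int = 30,
        seed: int = 0,
        batch_size: int = 2048,
    ):
        self.algorithm = algorithm
        self.dim = dim
        self.window = window
        self.min_count = min_count
        self.learning_rate = learning_rate
        self.negative = negative
        self.epochs = epochs
        self.seed = seed
        self.batch_size = batch_size

    def _effective_lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        # CBOW spreads each update over the whole context, so it takes a
        # larger step per example (the classic trainers double it likewise)
        return 0.2 if self.algorithm == "cbow" else 0.1

    def _train(self, encoded: list[np.ndarray]) -> np.ndarray:
        if self.algorithm not in ("cbow", "skipgram"):
            raise ValueError(f"algorithm must be cbow or skipgram, got {self.algorithm!r}")
        return train_sgns(
            encoded,
            self.counts_,
            algorithm=self.algorithm,
            dim=self.dim,
            window=self.window,
            learning_rate=self._effective_lr(),
            epochs=self.epochs,
            negative=self.negative,
            seed=self.seed,
            batch_size=self.batch_size,
        )

    def _hyperparams(self) -> Hyperparams:
        return Hyperparams(
            algorithm=self.algorithm,
            window=self.window,
            dim=self.dim,
            learning_rate=self.learning_rate,
            min_count=self.min_count,
            negative=self.negative,
            epochs=self.epochs,
            seed=self.seed,
        )


class GloVe(_BaseEmbedding):
    """Global-vectors trainer: weighted least-squares factorization of the
    windowed co-occurrence matrix with AdaGrad (in-repo numpy trainer)."""

    def __init__(
        self,
        dim: int = 100,
        window: int = 10,
        min_count: int = 1,
        learning_rate: float = 0.05,
        alpha: float = 0.75,
        x_max: float = 10.0,
        epochs: int = 150,
        seed: int = 0,
    ):
        self.dim = dim
        self.window = window
        self.min_count = min_count
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.x_max = x_max
        self.epochs = epochs
        self.seed = seed

    def _train(self, encoded: list[np.ndarray]) -> np.ndarray:
        return train_glove(
            encoded,
            len(self.counts_),
            dim=self.dim,
            window=self.window,
            learning_rate=self.learning_rate,
            alpha=self.alpha,
            x_max=self.x_max,
            epochs=self.epochs,
            seed=self.seed,
        )

    def _hyperparams(self) -> Hyperparams:
        return Hyperparams(
            algorithm="glove",
            window=self.window,
            dim=self.dim,
            learning_rate=self.learning_rate,
            min_count=self.min_count,
            glove_alpha=self.alpha,
            glove_x_max=self.x_max,
            epochs=self.epochs,
            seed=self.seed,
        )


def train_embedding(corpus, hp: Hyperparams) -> EmbeddingModel:
    """Train one embedding model on a corpus under the given hyperparameters."""
    if hp.algorithm == "glove":
        est = GloVe(
            dim=hp.dim,
            window=hp.window,
            min_count=hp.min_count,
            learning_rate=0.05 if hp.learning_rate is None else hp.learning_rate,
            alpha=hp.glove_alpha,
            x_max=hp.glove_x_max,
            epochs=150 if hp.epochs is None else hp.epochs,
            seed=hp.seed,
        )
    else:
        est = Word2Vec(
            algorithm=hp.algorithm,
            dim=hp.dim,
            window=hp.window,
            min_count=hp.min_count,
            learning_rate=hp.learning_rate,
            negative=hp.negative,
            epochs=30 if hp.epochs is None else hp.epochs,
            seed=hp.seed,
        )
    return est.fit(corpus).to_model()


# ---------------------------------------------------------------------------
# word2vec text format


def save_word2vec_format(model: EmbeddingModel, path: str | Path) -> None:
    """``vocab_size dim`` header, then ``token v1 ... vd`` per line."""
    order = sorted(model.index, key=model.index.get)
    with open(path, "w") as fh:
        fh.write(f"{len(order)} {model.dim}\n")
        for tok in order:
            vals = " ".join(f"{x:.8f}" for x in model.vectors[model.index[tok]])
            fh.write(f"{tok} {vals}\n")


def load_word2vec_format(path: str | Path) -> EmbeddingModel:
    with open(path) as fh:
        header = fh.readline().split()
        n, dim = int(header[0]), int(header[1])
        index: dict[str, int] = {}
        vectors = np.empty((n, dim), dtype=np.float32)
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split(" ")
            index[parts[0]] = i
            vectors[i] = np.array(parts[1 : dim + 1], dtype=np.float32)
    if len(index) != n:
        raise ValueError(f"header promised {n} vectors, file held {len(index)}")
    return EmbeddingModel(index=index, vectors=vectors)
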