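"""Full-name reconstruction from surviving name tokens.

An imperfect de-identifier leaves a small set of name tokens in the training
corpus.  Because the two tokens of one person's name occur in the same
contexts (notes about that person), their embedding vectors end up close.
The attack therefore ranks all unordered token pairs by embedding distance,
ascending; pairs near the top of the list are candidate full names, and the
fraction of the first *k* that are real names measures leakage.

The attacker's estimate of how many full names exist — absent ground truth —
is half the token count (two tokens per name, no sharing assumed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .corpus import GroundTruth
from .embeddings import EmbeddingModel

__all__ = [
    "CandidatePair",
    "rank_candidate_pairs",
    "greedy_filter_pairs",
    "evaluate_reconstruction",
    "expected_name_count",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidatePair:
    """Unordered token pair in canonical (lexicographically sorted) form."""

    token_a: str
    token_b: str
    distance: float

    def __post_init__(self) -> None:
        if not self.token_a < self.token_b:
            raise ValueError("tokens must satisfy token_a < token_b (and differ)")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.token_a, self.token_b)


def rank_candidate_pairs(
    model: EmbeddingModel,
    name_tokens: Iterable[str],
    metric: str = "cosine",
) -> list[CandidatePair]:
    """All C(T, 2) unordered pairs sorted ascending by distance.

    Ties are broken lexicographically by (token_a, token_b).  Tokens missing
    from the vocabulary are dropped with a logged warning.
    """
    requested = sorted(set(name_tokens))
    tokens = [t for t in requested if t in model]
    dropped = [t for t in requested if t not in model]
    if dropped:
        logger.warning("dropping %d name tokens missing from vocabulary: %s",
                       len(dropped), dropped[:10])
    if len(tokens) < 2:
        raise ValueError("need at least 2 in-vocabulary name tokens to pair")

    X = np.asarray([model.vector(t) for t in tokens], dtype=np.float64)
    if metric == "cosine" and np.any(np.linalg.norm(X, axis=1) == 0.0):
        raise ValueError("cosine distance undefined for the zero vector")
    dists = pdist(X, metric=metric)
    pairs = [
        CandidatePair(tokens[i], tokens[j], float(d))
        for (i, j), d in zip(combinations(range(len(tokens)), 2), dists)
    ]
    pairs.sort(key=lambda p: (p.distance, p.token_a, p.token_b))
    return pairs


def greedy_filter_pairs(pairs: Sequence[CandidatePair]) -> list[CandidatePair]:
    """Exclusive variant: walk the ranking, consume each token at most once."""
    used: set[str] = set()
    kept = []
    for p in pairs:
        if p.token_a not in used and p.token_b not in used:
            kept.append(p)
            used.update(p.pair)
    return kept


def evaluate_reconstruction(
    pairs: Sequence[CandidatePair],
    truth: GroundTruth | set[tuple[str, str]],
    k: int,
) -> tuple[int, float]:
    """Count true full names among the first ``k`` ranked pairs.

    Returns ``(n_true, n_true / k)``.  A token may appear in several counted
    pairs (the ranking is not exclusive).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the {len(pairs)} available pairs")
    true_names = truth.retained_full_names if isinstance(truth, GroundTruth) else set(truth)
    true_names = {tuple(sorted(p)) for p in true_names}
    n_true = sum(1 for p in pairs[:k] if p.pair in true_names)
    return n_true, n_true / k


def expected_name_count(n_tokens: int) -> int:
    """Attacker's estimate of full names: half the surviving token count."""
    if n_tokens < 0:
        raise ValueError("n_tokens must be >= 0")
    return n_tokens // 2
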