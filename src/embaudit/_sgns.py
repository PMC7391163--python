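"""Minibatched negative-sampling trainer for CBOW and Skipgram.

Plain-numpy implementation of word2vec-style training: a fixed symmetric
context window, the unigram^0.75 noise distribution, logistic loss with k
negative samples per positive example, and a linearly decaying learning
rate.  Batches are processed with gather/scatter (``np.add.at``) so the whole
run is vectorized and, with a fixed seed, bit-reproducible on one thread.

Deliberate simplifications relative to the original C tool: the window is
not randomly shrunk per position and no frequent-word subsampling is applied
(both add variance without changing what the audit measures).  Because very
frequent tokens collide many times inside one minibatch, per-row gradients
are scatter-AVERAGED rather than summed before the step — summing would
multiply the effective learning rate of hot tokens by their within-batch
count and destabilize training.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _scatter_step(P: np.ndarray, idx: np.ndarray, grads: np.ndarray, lr: float) -> None:
    """Apply one averaged gradient step per unique row index."""
    uniq, inv = np.unique(idx, return_inverse=True)
    acc = np.zeros((len(uniq), P.shape[1]), dtype=P.dtype)
    np.add.at(acc, inv, grads)
    cnt = np.bincount(inv).astype(P.dtype)
    P[uniq] -= lr * acc / cnt[:, None]


def _skipgram_pairs(sentences: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for sent in sentences:
        for off in range(1, window + 1):
            if len(sent) <= off:
                continue
            a, b = sent[:-off], sent[off:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        raise ValueError("corpus yields no training pairs at this window")
    return (
        np.concatenate(centers).astype(np.int32),
        np.concatenate(contexts).astype(np.int32),
    )


def _cbow_examples(sentences: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per position: center id, padded context-id matrix, context mask."""
    centers, ctx_rows = [], []
    width = 2 * window
    for sent in sentences:
        n = len(sent)
        if n < 2:
            continue
        ctx = np.full((n, width), -1, dtype=np.int32)
        col = 0
        for off in range(1, window + 1):
            ctx[off:, col] = sent[:-off] if off < n else -1
            col += 1
            ctx[:-off, col] = sent[off:] if off < n else -1
            col += 1
        centers.append(sent.astype(np.int32))
        ctx_rows.append(ctx)
    if not centers:
        raise ValueError("corpus yields no training examples at this window")
    centers = np.concatenate(centers)
    ctx = np.vstack(ctx_rows)
    mask = (ctx >= 0).astype(np.float32)
    return centers, ctx, mask


def train_sgns(
    sentences: list[np.ndarray],
    counts: np.ndarray,
    *,
    algorithm: str = "skipgram",
    dim: int = 100,
    window: int = 5,
    learning_rate: float = 0.025,
    epochs: int = 5,
    negative: int = 5,
    seed: int = 0,
    batch_size: int = 2048,
) -> np.ndarray:
    """Train input vectors; returns a float32 array of shape (vocab, dim)."""
    n_vocab = len(counts)
    rng = np.random.default_rng(seed)
    W = ((rng.random((n_vocab, dim)) - 0.5) / dim).astype(np.float32)  # input
    C = np.zeros((n_vocab, dim), dtype=np.float32)  # output/context

    noise = counts.astype(np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    noise_cdf[-1] = 1.0

    if algorithm == "skipgram":
        centers, contexts = _skipgram_pairs(sentences, window)
        n_examples = len(centers)
    elif algorithm == "cbow":
        centers, ctx, mask = _cbow_examples(sentences, window)
        ctx_safe = np.maximum(ctx, 0)
        cnt = np.maximum(mask.sum(axis=1), 1.0)
        n_examples = len(centers)
    else:
        raise ValueError(f"unknown SGNS algorithm {algorithm!r}")

    total_batches = max(1, epochs * ((n_examples + batch_size - 1) // batch_size))
    step = 0
    lr0 = learning_rate

    for _epoch in range(epochs):
        order = rng.permutation(n_examples)
        for start in range(0, n_examples, batch_size):
            b = order[start : start + batch_size]
            lr = lr0 * max(1.0 - step / total_batches, 1e-4)
            step += 1
            neg = np.searchsorted(noise_cdf, rng.random((len(b), negative))).astype(np.int32)

            if algorithm == "skipgram":
                h = W[centers[b]]  # (B, d)
                h_src = centers[b]
                out_idx = np.concatenate([contexts[b][:, None], neg], axis=1)
            else:
                rows = ctx_safe[b]  # (B, 2w)
                m = mask[b]
                h = (W[rows] * m[:, :, None]).sum(axis=1) / cnt[b][:, None]
                out_idx = np.concatenate([centers[b][:, None], neg], axis=1)

            u = C[out_idx]  # (B, 1+k, d)
            g = expit(np.einsum("bkd,bd->bk", u, h, optimize=True)).astype(np.float32)
            g[:, 0] -= 1.0  # d(logloss)/d(score); first column is the positive

            grad_h = np.einsum("bk,bkd->bd", g, u, optimize=True)
            grad_u = g[:, :, None] * h[:, None, :]
            _scatter_step(C, out_idx.ravel(), grad_u.reshape(-1, dim), lr)
            if algorithm == "skipgram":
                _scatter_step(W, h_src, grad_h, lr)
            else:
                per_ctx = (grad_h / cnt[b][:, None])[:, None, :] * m[:, :, None]
                # padded slots carry zero gradient; route them to row 0 harmlessly
                _scatter_step(W, rows.ravel(), per_ctx.reshape(-1, dim), lr)

    return W
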