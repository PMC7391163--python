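"""Minimal GloVe trainer: co-occurrence accumulation + AdaGrad least squares.

Follows the standard recipe: symmetric window with 1/distance co-occurrence
weighting, loss  f(x_ij) (w_i . w~_j + b_i + b~_j - log x_ij)^2  with
f(x) = min(1, (x / x_max)^alpha), optimised by AdaGrad over the nonzero
cells, and final vectors w + w~.  Everything is vectorized numpy and
deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np


def _ada_step(P: np.ndarray, G: np.ndarray, idx: np.ndarray, grads: np.ndarray, lr: float) -> None:
    """AdaGrad step on the scatter-MEAN gradient per unique row.

    Averaging (rather than summing) within-batch collisions keeps the update
    of very frequent tokens bounded, mirroring the sequential reference
    implementation's stability.
    """
    uniq, inv = np.unique(idx, return_inverse=True)
    acc = np.zeros((len(uniq),) + grads.shape[1:], dtype=P.dtype)
    np.add.at(acc, inv, grads)
    cnt = np.bincount(inv).astype(P.dtype).reshape((-1,) + (1,) * (grads.ndim - 1))
    mean = acc / cnt
    P[uniq] -= lr * mean / np.sqrt(G[uniq])
    G[uniq] += mean**2


def build_cooccurrence(
    sentences: list[np.ndarray], n_vocab: int, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate ordered co-occurrence triples (i, j, x) over the corpus."""
    keys_parts, w_parts = [], []
    for sent in sentences:
        s = sent.astype(np.int64)
        for off in range(1, window + 1):
            if len(s) <= off:
                continue
            a, b = s[:-off], s[off:]
            weight = 1.0 / off
            # both directions: X is symmetric
            keys_parts.append(a * n_vocab + b)
            keys_parts.append(b * n_vocab + a)
            w_parts.append(np.full(len(a), weight))
            w_parts.append(np.full(len(a), weight))
    if not keys_parts:
        raise ValueError("corpus yields no co-occurrences at this window")
    keys = np.concatenate(keys_parts)
    weights = np.concatenate(w_parts)
    uniq, inv = np.unique(keys, return_inverse=True)
    x = np.bincount(inv, weights=weights, minlength=len(uniq))
    i_idx = (uniq // n_vocab).astype(np.int32)
    j_idx = (uniq % n_vocab).astype(np.int32)
    return i_idx, j_idx, x


def train_glove(
    sentences: list[np.ndarray],
    n_vocab: int,
    *,
    dim: int = 100,
    window: int = 10,
    learning_rate: float = 0.05,
    alpha: float = 0.75,
    x_max: float = 10.0,
    epochs: int = 30,
    seed: int = 0,
    batch_size: int = 65536,
) -> np.ndarray:
    i_idx, j_idx, x = build_cooccurrence(sentences, n_vocab, window)
    logx = np.log(x).astype(np.float32)
    fwt = np.minimum(1.0, (x / x_max) ** alpha).astype(np.float32)

    rng = np.random.default_rng(seed)
    scale = 0.5 / dim
    W = (rng.random((n_vocab, dim)).astype(np.float32) - 0.5) * scale
    Wc = (rng.random((n_vocab, dim)).astype(np.float32) - 0.5) * scale
    b = np.zeros(n_vocab, dtype=np.float32)
    bc = np.zeros(n_vocab, dtype=np.float32)
    # AdaGrad accumulators
    gW = np.full((n_vocab, dim), 1.0, dtype=np.float32)
    gWc = np.full((n_vocab, dim), 1.0, dtype=np.float32)
    gb = np.full(n_vocab, 1.0, dtype=np.float32)
    gbc = np.full(n_vocab, 1.0, dtype=np.float32)

    nnz = len(x)
    for _epoch in range(epochs):
        order = rng.permutation(nnz)
        for start in range(0, nnz, batch_size):
            s = order[start : start + batch_size]
            ii, jj = i_idx[s], j_idx[s]
            wi, wj = W[ii], Wc[jj]
            err = (wi * wj).sum(axis=1) + b[ii] + bc[jj] - logx[s]
            g = fwt[s] * err  # (B,)

            grad_wi = g[:, None] * wj
            grad_wj = g[:, None] * wi
            _ada_step(W, gW, ii, grad_wi, learning_rate)
            _ada_step(Wc, gWc, jj, grad_wj, learning_rate)
            _ada_step(b, gb, ii, g, learning_rate)
            _ada_step(bc, gbc, jj, g, learning_rate)

    return W + Wc
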