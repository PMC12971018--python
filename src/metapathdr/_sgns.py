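"""Numba kernel for skip-gram with (type-aware) negative sampling.

Single-threaded SGD in the word2vec style: linear learning-rate decay, a
uniformly shrunk context window per center token, sigmoid table-free updates
with +/-6 logit clipping.  Negatives for a context token are drawn from a
unigram^0.75 table restricted to that token's node type (the heterogeneous
variant); a single shared table recovers the vanilla skip-gram.

Randomness comes from an xorshift64* generator seeded explicitly, so a fixed
seed yields bit-identical embeddings.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MULT = np.uint64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _xorshift(state):
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state &= np.uint64(0xFFFFFFFFFFFFFFFF)
    state ^= state >> np.uint64(27)
    return state


@njit(cache=True)
def train_sgns(
    tokens,  # int32[:], concatenated walks
    offsets,  # int64[:], walk boundaries (n_walks + 1)
    token_type,  # int8[:], node-type id per vocab index
    neg_table,  # int32[:], concatenated per-type sampling tables
    table_offsets,  # int64[:], per-type slices into neg_table (n_types + 1)
    syn0,  # float32[:, :], input vectors (updated in place)
    syn1,  # float32[:, :], output vectors (updated in place)
    window,
    epochs,
    negative,
    alpha0,
    seed,
):
    dim = syn0.shape[1]
    n_tokens = tokens.shape[0]
    total = np.float64(epochs * n_tokens)
    min_alpha = alpha0 * 1e-4
    state = np.uint64(seed * 2 + 1)
    neu1e = np.zeros(dim, dtype=np.float32)
    processed = 0
    for _ in range(epochs):
        for s in range(offsets.shape[0] - 1):
            start = offsets[s]
            end = offsets[s + 1]
            for pos in range(start, end):
                alpha = alpha0 * (1.0 - processed / total)
                if alpha < min_alpha:
                    alpha = min_alpha
                processed += 1
                center = tokens[pos]
                state = _xorshift(state)
                shrink = np.int64(state % np.uint64(window))
                lo = pos - window + shrink
                hi = pos + window - shrink
                if lo < start:
                    lo = start
                if hi > end - 1:
                    hi = end - 1
                for j in range(lo, hi + 1):
                    if j == pos:
                        continue
                    context = tokens[j]
                    ttype = token_type[context]
                    t_lo = table_offsets[ttype]
                    t_hi = table_offsets[ttype + 1]
                    t_size = t_hi - t_lo
                    for k in range(dim):
                        neu1e[k] = 0.0
                    for d in range(negative + 1):
                        if d == 0:
                            target = context
                            label = 1.0
                        else:
                            if t_size <= 0:
                                continue
                            state = _xorshift(state)
                            target = neg_table[
                                t_lo + np.int64(state % np.uint64(t_size))
                            ]
                            if target == context:
                                continue
                            label = 0.0
                        f = np.float64(0.0)
                        for k in range(dim):
                            f += syn0[center, k] * syn1[target, k]
                        if f > 6.0:
                            g = (label - 1.0) * alpha
                        elif f < -6.0:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-f))) * alpha
                        gf = np.float32(g)
                        for k in range(dim):
                            neu1e[k] += gf * syn1[target, k]
                        for k in range(dim):
                            syn1[target, k] += gf * syn0[center, k]
                    for k in range(dim):
                        syn0[center, k] += neu1e[k]


def init_vectors(vocab_size: int, dim: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """word2vec-style init: uniform(-0.5, 0.5)/dim inputs, zero outputs."""
    rng = np.random.default_rng(seed)
    syn0 = ((rng.random((vocab_size, dim), dtype=np.float64) - 0.5) / dim).astype(
        np.float32
    )
    syn1 = np.zeros((vocab_size, dim), dtype=np.float32)
    return syn0, syn1


def build_negative_tables(
    counts: np.ndarray, types: np.ndarray, n_types: int, table_size: int = 100_000
) -> tuple[np.ndarray, np.ndarray]:
    """Per-type unigram^0.75 sampling tables, concatenated.

    Returns (neg_table, table_offsets) where table_offsets[t]:table_offsets[t+1]
    slices the table for node-type id t.  Empty types get empty slices.
    """
    tables: list[np.ndarray] = []
    offsets = np.zeros(n_types + 1, dtype=np.int64)
    for t in range(n_types):
        members = np.flatnonzero(types == t)
        if members.size == 0:
            offsets[t + 1] = offsets[t]
            tables.append(np.empty(0, dtype=np.int32))
            continue
        weights = counts[members].astype(np.float64) ** 0.75
        cum = np.cumsum(weights / weights.sum())
        grid = (np.arange(table_size) + 0.5) / table_size
        idx = np.searchsorted(cum, grid, side="right")
        idx = np.minimum(idx, members.size - 1)
        tables.append(members[idx].astype(np.int32))
        offsets[t + 1] = offsets[t] + table_size
    return np.concatenate(tables) if tables else np.empty(0, dtype=np.int32), offsets
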