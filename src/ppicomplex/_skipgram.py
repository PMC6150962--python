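"""Numba-jitted skip-gram with negative sampling for walk corpora.

Single-threaded SGD in corpus order with a linearly decaying learning rate,
so a fixed seed yields bit-identical embeddings.  Negative targets are drawn
from the unigram^0.75 distribution via an alias table.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _sgd(centers, contexts, w_in, w_out, alias_j, alias_q, n_negative,
         epochs, alpha0, alpha_min, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_pairs = centers.shape[0]
    d = w_in.shape[1]
    vocab = alias_j.shape[0]
    total = n_pairs * epochs
    step = 0
    neu1e = np.empty(d, dtype=np.float64)
    for _ in range(epochs):
        for i in range(n_pairs):
            alpha = alpha0 - (alpha0 - alpha_min) * (step / total)
            step += 1
            c = centers[i]
            pos = contexts[i]
            for j in range(d):
                neu1e[j] = 0.0
            for neg in range(n_negative + 1):
                if neg == 0:
                    target = pos
                    label = 1.0
                else:
                    k = int(np.random.random() * vocab)
                    if k >= vocab:
                        k = vocab - 1
                    if np.random.random() < alias_q[k]:
                        target = k
                    else:
                        target = alias_j[k]
                    if target == pos:
                        continue
                    label = 0.0
                f = 0.0
                for j in range(d):
                    f += w_in[c, j] * w_out[target, j]
                if f > 6.0:
                    s = 1.0
                elif f < -6.0:
                    s = 0.0
                else:
                    s = 1.0 / (1.0 + math.exp(-f))
                g = (label - s) * alpha
                for j in range(d):
                    neu1e[j] += g * w_out[target, j]
                    w_out[target, j] += g * w_in[c, j]
            for j in range(d):
                w_in[c, j] += neu1e[j]


def train_pairs(centers, contexts, vocab_size, d, noise_alias, n_negative,
                epochs, alpha0, alpha_min, seed):
    """Run skip-gram SGD over (center, context) index pairs.

    Returns the input-vector matrix (vocab_size x d), the conventional
    word-vector output.
    """
    rng = np.random.RandomState(seed % (2**31 - 1))
    w_in = (rng.rand(vocab_size, d) - 0.5) / d
    w_out = np.zeros((vocab_size, d), dtype=np.float64)
    alias_j, alias_q = noise_alias
    _sgd(
        np.ascontiguousarray(centers, dtype=np.int64),
        np.ascontiguousarray(contexts, dtype=np.int64),
        w_in, w_out,
        np.ascontiguousarray(alias_j, dtype=np.int64),
        np.ascontiguousarray(alias_q, dtype=np.float64),
        int(n_negative), int(epochs), float(alpha0), float(alpha_min),
        int(seed % (2**31 - 1)),
    )
    return w_in
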