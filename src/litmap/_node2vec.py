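"""Numba kernels for node2vec: biased second-order random walks and
skip-gram with negative sampling (SGNS).

Single-threaded and seeded end-to-end, so a fixed seed gives bit-identical
embeddings. Transition probabilities within a walk are proportional to the
edge weight times the node2vec bias: 1/p for returning to the previous
node, 1 for nodes adjacent to the previous node, 1/q otherwise.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _contains(indices, lo, hi, x):
    """Binary search for x in the sorted slice indices[lo:hi]."""
    while lo < hi:
        mid = (lo + hi) // 2
        v = indices[mid]
        if v == x:
            return True
        if v < x:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def generate_walks(indptr, indices, weights, walk_length, walks_per_node, p, q, seed):
    np.random.seed(seed)
    n_nodes = indptr.shape[0] - 1
    walks = np.empty((n_nodes * walks_per_node, walk_length), dtype=np.int32)
    probs = np.empty(indices.shape[0])  # scratch, sized at max degree use
    w = 0
    for rep in range(walks_per_node):
        for start in range(n_nodes):
            walks[w, 0] = start
            prev = -1
            cur = start
            for step in range(1, walk_length):
                lo, hi = indptr[cur], indptr[cur + 1]
                deg = hi - lo
                if deg == 0:
                    walks[w, step] = cur  # isolated node: self-only walk
                    continue
                total = 0.0
                for e in range(lo, hi):
                    nxt = indices[e]
                    bias = 1.0
                    if prev >= 0:
                        if nxt == prev:
                            bias = 1.0 / p
                        elif _contains(indices, indptr[prev], indptr[prev + 1], nxt):
                            bias = 1.0
                        else:
                            bias = 1.0 / q
                    pr = weights[e] * bias
                    total += pr
                    probs[e - lo] = total
                r = np.random.random() * total
                chosen = indices[hi - 1]
                for e in range(deg):
                    if r <= probs[e]:
                        chosen = indices[lo + e]
                        break
                walks[w, step] = chosen
                prev = cur
                cur = chosen
            w += 1
    return walks


@njit(cache=True)
def train_sgns(walks, n_nodes, dim, window, epochs, negative, alpha0, neg_cum, seed):
    """Skip-gram with negative sampling over the walk corpus.

    ``neg_cum`` is the cumulative unigram^0.75 noise distribution. The
    learning rate decays linearly to alpha0/1e4; the input vectors are the
    embedding.
    """
    np.random.seed(seed + 1)
    w_in = (np.random.random((n_nodes, dim)) - 0.5) / dim
    w_out = np.zeros((n_nodes, dim))
    grad = np.empty(dim)

    n_walks, walk_len = walks.shape
    total_steps = epochs * n_walks * walk_len
    step = 0
    for _ep in range(epochs):
        for iw in range(n_walks):
            for i in range(walk_len):
                alpha = alpha0 * (1.0 - step / (total_steps + 1))
                if alpha < alpha0 * 1e-4:
                    alpha = alpha0 * 1e-4
                step += 1
                center = walks[iw, i]
                b = np.random.randint(window)  # reduced window, word2vec style
                jlo = i - window + b
                jhi = i + window - b
                if jlo < 0:
                    jlo = 0
                if jhi > walk_len - 1:
                    jhi = walk_len - 1
                for j in range(jlo, jhi + 1):
                    if j == i:
                        continue
                    ctx = walks[iw, j]
                    for d in range(dim):
                        grad[d] = 0.0
                    for k in range(negative + 1):
                        if k == 0:
                            target = ctx
                            label = 1.0
                        else:
                            r = np.random.random()
                            target = np.searchsorted(neg_cum, r)
                            if target == ctx:
                                continue
                            label = 0.0
                        dot = 0.0
                        for d in range(dim):
                            dot += w_in[center, d] * w_out[target, d]
                        if dot > 6.0:
                            f = 1.0
                        elif dot < -6.0:
                            f = 0.0
                        else:
                            f = 1.0 / (1.0 + np.exp(-dot))
                        g = (label - f) * alpha
                        for d in range(dim):
                            grad[d] += g * w_out[target, d]
                            w_out[target, d] += g * w_in[center, d]
                    for d in range(dim):
                        w_in[center, d] += grad[d]
    return w_in
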