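"""Node embeddings via biased random walks + skip-gram; complex vectors.

The walk process is the standard second-order biased walk: from current node
``v`` reached from previous node ``t``, the unnormalized probability of moving
to neighbor ``x`` is ``w(v,x) * alpha`` where ``alpha = 1/p`` if ``x == t``
(return), ``1`` if ``x`` is adjacent to ``t``, and ``1/q`` otherwise.  Every
step is drawn in O(1) from a precomputed alias table.  Walks are fed to a
skip-gram model with negative sampling (window ``k``, dimension ``d``).

A complex vector summarizes a protein complex as a single d-vector by
column-wise pooling (max by default; min/average alternatives) of its member
embeddings, and cosine similarity between member vectors quantifies the
reliability of an interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np

from . import _skipgram
from .ppi_io import Complex

__all__ = [
    "Node2VecParams",
    "EmbeddingMatrix",
    "build_transition_probs",
    "simulate_walks",
    "train_embeddings",
    "cosine_similarity",
    "complex_vector",
]


@dataclass(frozen=True)
class Node2VecParams:
    """Biased-walk and skip-gram hyperparameters.

    Defaults follow the setting recommended for embedding structurally similar
    nodes close together on PPI networks: p=1, q=8 (strongly local,
    breadth-first-like walks), r=10 walks of length l=10 per node, window
    k=10, dimension d=64.  The trailing skip-gram knobs (negatives, epochs,
    learning rate) are conventional word2vec defaults.
    """

    p: float = 1.0
    q: float = 8.0
    r: int = 10
    l: int = 10
    k: int = 10
    d: int = 64
    negative: int = 5
    epochs: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.r < 1 or self.l < 2 or self.k < 1 or self.d < 1:
            raise ValueError("require r>=1, l>=2, k>=1, d>=1")
        if self.negative < 1 or self.epochs < 1:
            raise ValueError("require negative>=1, epochs>=1")


class EmbeddingMatrix:
    """Map from node ID to a d-dimensional embedding vector."""

    def __init__(self, vectors: Dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty embedding matrix")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError("inconsistent embedding dimensions")
        self._vectors = {n: np.asarray(v, dtype=float) for n, v in vectors.items()}
        self.d = dims.pop()

    def __contains__(self, node) -> bool:
        return node in self._vectors

    def __getitem__(self, node) -> np.ndarray:
        return self._vectors[node]

    def __len__(self) -> int:
        return len(self._vectors)

    def nodes(self) -> List[str]:
        return sorted(self._vectors)

    def get(self, node, zero_missing: bool = True) -> np.ndarray:
        """Vector for ``node``; missing nodes map to the zero vector."""
        vec = self._vectors.get(node)
        if vec is None:
            if not zero_missing:
                raise KeyError(node)
            return np.zeros(self.d)
        return vec

    def save(self, path) -> None:
        """Persist in word2vec text format: header ``N d``, then one node/line."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"{len(self._vectors)} {self.d}\n")
            for node in sorted(self._vectors):
                coords = " ".join(repr(float(x)) for x in self._vectors[node])
                fh.write(f"{node} {coords}\n")

    @classmethod
    def load(cls, path) -> "EmbeddingMatrix":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            vectors = {}
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
                if len(vectors[parts[0]]) != d:
                    raise ValueError(f"vector for {parts[0]} has wrong dimension")
        if len(vectors) != n:
            raise ValueError("embedding file header/record count mismatch")
        return cls(vectors)


# ---------------------------------------------------------------------------
# Alias sampling


def _alias_setup(probs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Build Walker alias tables for a discrete distribution (O(n) setup)."""
    n = len(probs)
    q = np.zeros(n)
    j = np.zeros(n, dtype=np.int64)
    scaled = np.asarray(probs, dtype=float) * n
    smaller = [i for i in range(n) if scaled[i] < 1.0]
    larger = [i for i in range(n) if scaled[i] >= 1.0]
    while smaller and larger:
        small = smaller.pop()
        large = larger.pop()
        q[small] = scaled[small]
        j[small] = large
        scaled[large] = scaled[large] - (1.0 - scaled[small])
        if scaled[large] < 1.0:
            smaller.append(large)
        else:
            larger.append(large)
    for i in larger + smaller:
        q[i] = 1.0
    return j, q


def _alias_draw(j: np.ndarray, q: np.ndarray, rng: np.random.Generator) -> int:
    k = int(rng.integers(len(j)))
    return k if rng.random() < q[k] else int(j[k])


class TransitionProbs:
    """Alias-table transition structure for second-order biased walks.

    ``first[v]`` samples the first step out of ``v`` (weight-proportional);
    ``second[(t, v)]`` samples the next step from ``v`` given previous ``t``.
    """

    def __init__(self, first, second, neighbors):
        self.first = first
        self.second = second
        self.neighbors = neighbors

    def step_distribution(self, t, v) -> Dict[str, float]:
        """Explicit next-step distribution from ``v`` given previous ``t``."""
        nbrs, j, q = self.second[(t, v)]
        probs = _alias_probs(j, q)
        return dict(zip(nbrs, probs))


def _alias_probs(j: np.ndarray, q: np.ndarray) -> np.ndarray:
    # Invert the alias table back to the probability vector.
    n = len(j)
    probs = np.array(q, dtype=float)
    for i in range(n):
        if q[i] < 1.0:
            probs[j[i]] += 1.0 - q[i]
    return probs / n


def build_transition_probs(net: nx.Graph, params: Node2VecParams) -> TransitionProbs:
    """Precompute alias tables for every node and ordered edge of ``net``."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    adj = {v: sorted(net[v]) for v in net}
    adj_sets = {v: set(nbrs) for v, nbrs in adj.items()}

    def edge_weight(u, v):
        return float(net[u][v].get("weight", 1.0))

    first = {}
    for v in net:
        nbrs = adj[v]
        if not nbrs:
            first[v] = (nbrs, None, None)
            continue
        w = np.array([edge_weight(v, x) for x in nbrs])
        j, q = _alias_setup(w / w.sum())
        first[v] = (nbrs, j, q)

    second = {}
    for t, v in net.edges():
        for prev, cur in ((t, v), (v, t)):
            nbrs = adj[cur]
            w = np.empty(len(nbrs))
            for i, x in enumerate(nbrs):
                if x == prev:
                    alpha = 1.0 / params.p
                elif x in adj_sets[prev]:
                    alpha = 1.0
                else:
                    alpha = 1.0 / params.q
                w[i] = edge_weight(cur, x) * alpha
            j, q = _alias_setup(w / w.sum())
            second[(prev, cur)] = (nbrs, j, q)
    return TransitionProbs(first, second, adj)


def simulate_walks(net: nx.Graph, params: Node2VecParams, seed: int,
                   probs: Optional[TransitionProbs] = None) -> List[List[str]]:
    """Generate ``r`` biased walks of length ``l`` from every node.

    Walks from isolated nodes truncate to the single start node.  The same
    seed reproduces the identical corpus.
    """
    if probs is None:
        probs = build_transition_probs(net, params)
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    walks: List[List[str]] = []
    for _ in range(params.r):
        order = rng.permutation(len(nodes))
        for idx in order:
            start = nodes[idx]
            walk = [start]
            nbrs, j, q = probs.first[start]
            if not nbrs:
                walks.append(walk)
                continue
            walk.append(nbrs[_alias_draw(j, q, rng)])
            while len(walk) < params.l:
                prev, cur = walk[-2], walk[-1]
                nbrs, j, q = probs.second[(prev, cur)]
                walk.append(nbrs[_alias_draw(j, q, rng)])
            walks.append(walk)
    return walks


def train_embeddings(walks: List[List[str]], params: Node2VecParams,
                     seed: int) -> EmbeddingMatrix:
    """Train skip-gram embeddings over a walk corpus.

    Only nodes appearing in at least one walk receive a vector; callers
    needing a full matrix handle missing nodes (e.g. zero-vector fallback).
    Fixed seed + single-threaded SGD gives identical matrices across runs.
    """
    if not walks:
        raise ValueError("empty walk corpus")
    counts: Dict[str, int] = {}
    for walk in walks:
        for node in walk:
            counts[node] = counts.get(node, 0) + 1
    vocab = sorted(counts)
    index = {n: i for i, n in enumerate(vocab)}

    centers: List[int] = []
    contexts: List[int] = []
    k = params.k
    for walk in walks:
        ids = [index[n] for n in walk]
        for i, c in enumerate(ids):
            lo = max(0, i - k)
            hi = min(len(ids), i + k + 1)
            for jx in range(lo, hi):
                if jx != i:
                    centers.append(c)
                    contexts.append(ids[jx])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(centers))
    centers, contexts = centers[order], contexts[order]

    freq = np.array([counts[n] for n in vocab], dtype=float) ** 0.75
    noise_alias = _alias_setup(freq / freq.sum())
    w = _skipgram.train_pairs(
        centers, contexts, len(vocab), params.d, noise_alias,
        params.negative, params.epochs, params.alpha, params.min_alpha,
        int(rng.integers(0, 2**31 - 1)),
    )
    trained = set(centers.tolist()) | set(contexts.tolist())
    skipped = len(vocab) - len(trained)
    if skipped:
        warnings.warn(f"{skipped} nodes had no walk context and were not embedded")
    return EmbeddingMatrix({n: w[i] for n, i in index.items() if i in trained})


def embed_network(net: nx.Graph, params: Node2VecParams, seed: int) -> EmbeddingMatrix:
    """Convenience: walks + skip-gram on ``net`` in one call.

    Isolated nodes never co-occur with a context and therefore receive no
    vector; downstream consumers fall back to the zero vector for them.
    """
    walks = simulate_walks(net, params, seed)
    return train_embeddings(walks, params, seed)


# ---------------------------------------------------------------------------
# Similarity and complex vectors


def cosine_similarity(x, y) -> float:
    """Cosine of the angle between two vectors; 0 if either is the zero vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    nx_ = np.sqrt(np.dot(x, x))
    ny_ = np.sqrt(np.dot(y, y))
    if nx_ == 0.0 or ny_ == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx_ * ny_))


_POOLERS = {"max": np.max, "min": np.min, "average": np.mean}


def complex_vector(cx: Complex, emb: EmbeddingMatrix,
                   strategy: str = "max") -> np.ndarray:
    """Pool member embeddings column-wise into a single complex vector.

    The member vectors are stacked into an m x d matrix and each column is
    reduced by ``strategy`` (max pooling by default, which empirically keeps
    the globally salient coordinates of the member set).
    """
    if strategy not in _POOLERS:
        raise ValueError(f"unknown pooling strategy: {strategy!r}")
    members = sorted(cx.members)
    if not members:
        raise ValueError("empty complex has no vector")
    missing = [m for m in members if m not in emb]
    if missing:
        raise KeyError(f"members without embeddings: {missing}")
    z = np.stack([emb[m] for m in members])
    return _POOLERS[strategy](z, axis=0)
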