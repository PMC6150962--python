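"""Link-prediction benchmark: edge hiding, pair scorers, rank evaluation.

A fraction of edges is hidden (uniformly among edges whose removal keeps the
network connected); each hidden edge (u,v) is then ranked by a pair scorer
against sampled non-neighbors of u, reporting the mean rank of the true
partner and Hits@N.  Scorers: embedding cosine similarity, the AdjustCD
common-neighbor score

    AdjustCD(u,v) = 2|N_u ∩ N_v| / (max(|N_u|, N_avg) + max(|N_v|, N_avg)),

with N_avg the mean neighborhood size, the iterative PE-measure

    p(k)_uv = 1 - prod_l (1 - p(k-1)_ul * p(k-1)_vl)   over common neighbors l,

initialized at the adjacency indicator and run for k=2 iterations, and a
random-embedding baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from .embedding import EmbeddingMatrix, cosine_similarity

__all__ = [
    "LinkPredResult",
    "hide_edges",
    "adjustcd_score",
    "pe_scores",
    "PairScoreMatrix",
    "cosine_pair_score",
    "CosineScorer",
    "AdjustCDScorer",
    "RandomScorer",
    "rank_evaluate",
]


@dataclass
class LinkPredResult:
    mean_ranking: float
    hits_at: Dict[int, float]
    n_hidden: int
    n_candidates_per_pair: int
    ranks: List[float] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "mean_ranking": self.mean_ranking,
            "hits_at": {str(k): v for k, v in sorted(self.hits_at.items())},
            "n_hidden": self.n_hidden,
            "n_candidates_per_pair": self.n_candidates_per_pair,
        }


def hide_edges(net: nx.Graph, fraction: float, seed: int):
    """Hide ``floor(fraction * |E|)`` edges, keeping the network connected.

    Works on the largest connected component (with a warning) if the input is
    disconnected.  Each removal is drawn uniformly from the currently
    removable (non-bridge) edges; if none remain before the target count is
    met, fewer edges are hidden with a warning.

    Returns ``(reduced_network, hidden_edges)``.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net):
        comp = max(nx.connected_components(net), key=lambda c: (len(c), sorted(c)))
        warnings.warn("network disconnected; hiding edges within the largest "
                      f"component ({len(comp)} of {net.number_of_nodes()} nodes)")
        net = net.subgraph(comp).copy()
    else:
        net = net.copy()
    rng = np.random.default_rng(seed)
    target = int(fraction * net.number_of_edges())
    hidden: List[Tuple[str, str]] = []
    while len(hidden) < target:
        bridges = set(frozenset(e) for e in nx.bridges(net))
        removable = sorted(
            tuple(sorted(e)) for e in net.edges() if frozenset(e) not in bridges
        )
        if not removable:
            warnings.warn(f"only {len(hidden)} of {target} edges could be "
                          "hidden without disconnecting the network")
            break
        u, v = removable[int(rng.integers(len(removable)))]
        net.remove_edge(u, v)
        hidden.append((u, v))
    return net, hidden


def adjustcd_score(net: nx.Graph, u, v) -> float:
    """AdjustCD common-neighbor score normalized by average neighborhood size."""
    if u not in net or v not in net:
        raise KeyError(f"node not in network: {u if u not in net else v!r}")
    nu, nv = set(net[u]), set(net[v])
    n_avg = 2.0 * net.number_of_edges() / net.number_of_nodes()
    return 2.0 * len(nu & nv) / (max(len(nu), n_avg) + max(len(nv), n_avg))


class PairScoreMatrix:
    """Dense symmetric pair-score map over a fixed node set."""

    def __init__(self, nodes: Sequence[str], matrix: np.ndarray):
        self.nodes = list(nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.matrix = matrix

    def __call__(self, u, v) -> float:
        return float(self.matrix[self.index[u], self.index[v]])


def pe_scores(net: nx.Graph, iterations: int = 2) -> PairScoreMatrix:
    """PE-measure scores after ``iterations`` rounds (adjacency start).

    The product in the update runs over nodes adjacent to both endpoints in
    the original network; pairs with no common neighbor score 0 (empty
    product).  The full symmetric score matrix is returned.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    nodes = sorted(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in net.edges():
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    p = a.copy()
    for _ in range(iterations):
        p_next = np.empty_like(p)
        for i in range(n):
            common_l = np.flatnonzero(a[i])          # l adjacent to u=i
            if common_l.size == 0:
                p_next[i] = 0.0
                continue
            terms = 1.0 - p[:, common_l] * p[i, common_l][None, :]
            # only l adjacent to v contributes to the product for pair (i, v)
            terms = np.where(a[:, common_l] > 0, terms, 1.0)
            p_next[i] = 1.0 - np.prod(terms, axis=1)
        p = p_next
    np.fill_diagonal(p, 0.0)
    return PairScoreMatrix(nodes, p)


def cosine_pair_score(emb: EmbeddingMatrix, u, v) -> float:
    """Cosine similarity of two nodes' embeddings (0, with warning, if missing)."""
    if u not in emb or v not in emb:
        warnings.warn(f"unembedded node in pair ({u}, {v}); score 0")
        return 0.0
    return cosine_similarity(emb[u], emb[v])


class CosineScorer:
    """Pair scorer delegating to embedding cosine similarity."""

    def __init__(self, emb: EmbeddingMatrix):
        self.emb = emb

    def __call__(self, u, v) -> float:
        return cosine_pair_score(self.emb, u, v)


class AdjustCDScorer:
    """Pair scorer computing AdjustCD on a fixed network (N_avg cached)."""

    def __init__(self, net: nx.Graph):
        self.adj = {v: set(net[v]) for v in net}
        self.n_avg = 2.0 * net.number_of_edges() / net.number_of_nodes()

    def __call__(self, u, v) -> float:
        nu, nv = self.adj[u], self.adj[v]
        return 2.0 * len(nu & nv) / (
            max(len(nu), self.n_avg) + max(len(nv), self.n_avg))


class RandomScorer:
    """Cosine similarity of random unit vectors — the random baseline."""

    def __init__(self, nodes: Sequence[str], d: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        vecs = rng.standard_normal((len(nodes), d))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        self.emb = EmbeddingMatrix({v: vecs[i] for i, v in enumerate(sorted(nodes))})

    def __call__(self, u, v) -> float:
        return cosine_similarity(self.emb[u], self.emb[v])


def rank_evaluate(scorer, reduced_net: nx.Graph,
                  hidden: Sequence[Tuple[str, str]], n_candidates: int = 100,
                  hits_levels: Sequence[int] = (1, 10, 50),
                  seed: int = 0) -> LinkPredResult:
    """Rank each hidden edge against sampled non-neighbor candidates.

    For a hidden edge (u, v), ``n_candidates`` nodes w that are not adjacent
    to u in the reduced network (and differ from u and v) are sampled; the
    true pair's score is ranked among the candidate scores (rank 1 best; ties
    take the mean rank).  Reports the mean rank and, per N, the percentage of
    hidden edges ranked in the top N.
    """
    if not hidden:
        raise ValueError("no hidden edges to evaluate")
    rng = np.random.default_rng(seed)
    nodes = sorted(reduced_net.nodes())
    ranks: List[float] = []
    shortfall = False
    for u, v in hidden:
        eligible = [w for w in nodes
                    if w != u and w != v and not reduced_net.has_edge(u, w)]
        if len(eligible) < n_candidates:
            shortfall = True
            sampled = eligible
        else:
            idx = rng.choice(len(eligible), size=n_candidates, replace=False)
            sampled = [eligible[i] for i in idx]
        s_true = scorer(u, v)
        cand = np.array([scorer(u, w) for w in sampled])
        greater = int((cand > s_true).sum())
        ties = int((cand == s_true).sum())
        ranks.append(greater + (ties + 2) / 2.0)
    if shortfall:
        warnings.warn("fewer eligible non-neighbors than requested candidates "
                      "for some hidden edges; used all available")
    ranks_arr = np.array(ranks)
    hits = {int(n): float(100.0 * (ranks_arr <= n).mean()) for n in hits_levels}
    return LinkPredResult(
        mean_ranking=float(ranks_arr.mean()),
        hits_at=hits,
        n_hidden=len(hidden),
        n_candidates_per_pair=n_candidates,
        ranks=ranks,
    )
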