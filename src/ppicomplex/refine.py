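"""Embedding-guided network refinement.

Interactions are weighted by the cosine similarity of their endpoints'
embeddings; low-similarity edges (likely noise) can then be filtered out, and
for each node the single most similar non-neighbor can be admitted as a new
edge when its similarity clears a threshold.  Both steps can be chained
(filter first, then augment the filtered network).

Comparison conventions: filtering keeps edges with weight >= threshold
(non-strict), augmentation admits a candidate only when similarity is
strictly greater than the threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .embedding import EmbeddingMatrix, cosine_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "RefinementConfig",
    "weight_edges",
    "filter_edges",
    "augment_edges",
    "refine",
]


@dataclass(frozen=True)
class RefinementConfig:
    """Filter/augment thresholds; order is always filter-then-add."""

    filter_thres: Optional[float] = None
    add_thres: Optional[float] = None

    def __post_init__(self):
        if self.filter_thres is None and self.add_thres is None:
            raise ValueError("at least one of filter_thres/add_thres must be set")
        for name in ("filter_thres", "add_thres"):
            val = getattr(self, name)
            if val is not None and not (-1.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [-1, 1]")


def weight_edges(net: nx.Graph, emb: EmbeddingMatrix) -> nx.Graph:
    """Return a copy of ``net`` with each edge weighted by endpoint cosine.

    Nodes without an embedding fall back to the zero vector, so their edges
    receive weight 0 (no evidence of reliability).
    """
    missing = [v for v in net if v not in emb]
    if missing:
        warnings.warn(f"{len(missing)} nodes lack embeddings; their edges get weight 0")
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    for u, v in net.edges():
        out.add_edge(u, v, weight=cosine_similarity(emb.get(u), emb.get(v)))
    return out


def filter_edges(wnet: nx.Graph, simi_thres: float) -> nx.Graph:
    """Keep exactly the edges with weight >= ``simi_thres``; nodes retained."""
    out = nx.Graph()
    out.add_nodes_from(wnet.nodes())
    removed = 0
    for u, v, data in wnet.edges(data=True):
        if "weight" not in data:
            raise ValueError(f"edge {u}-{v} carries no weight; weight the network first")
        if data["weight"] >= simi_thres:
            out.add_edge(u, v, **data)
        else:
            removed += 1
    logger.info("filter_edges: removed %d of %d edges at simi-thres %.3f",
                removed, wnet.number_of_edges(), simi_thres)
    return out


def augment_edges(net: nx.Graph, emb: EmbeddingMatrix,
                  simi_thres: float) -> nx.Graph:
    """Add, per node, its most cosine-similar non-neighbor when above threshold.

    For each node ``u`` the non-neighbor ``v*`` maximizing cosine similarity is
    found by exact search; the edge ``u-v*`` is added iff the similarity is
    strictly greater than ``simi_thres``.  Symmetric duplicates are added once.
    Nodes with a zero embedding contribute no candidate.
    """
    nodes = sorted(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    mat = np.stack([emb.get(v) for v in nodes])
    norms = np.linalg.norm(mat, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    unit = mat / safe[:, None]

    out = net.copy()
    weighted_base = any("weight" in d for _, _, d in net.edges(data=True))
    added = 0
    for i, u in enumerate(nodes):
        if norms[i] == 0.0:
            continue
        sims = unit @ unit[i]
        sims[i] = -np.inf
        for nbr in net[u]:
            sims[index[nbr]] = -np.inf
        sims[norms == 0.0] = -np.inf
        j = int(np.argmax(sims))
        if np.isfinite(sims[j]) and sims[j] > simi_thres:
            if not out.has_edge(u, nodes[j]):
                if weighted_base:
                    # a new edge's reliability is its embedding similarity
                    out.add_edge(u, nodes[j], weight=float(sims[j]))
                else:
                    out.add_edge(u, nodes[j])
                added += 1
    logger.info("augment_edges: added %d edges at simi-thres %.3f", added, simi_thres)
    return out


def refine(net: nx.Graph, emb: EmbeddingMatrix, config: RefinementConfig):
    """Weight, optionally filter, then optionally augment the network.

    Returns ``(refined_network, report)`` where the report records the edge
    counts removed/added and the thresholds applied.
    """
    weighted = weight_edges(net, emb)
    report = {
        "n_edges_in": net.number_of_edges(),
        "filter_thres": config.filter_thres,
        "add_thres": config.add_thres,
        "n_edges_removed": 0,
        "n_edges_added": 0,
    }
    current = weighted
    if config.filter_thres is not None:
        filtered = filter_edges(current, config.filter_thres)
        report["n_edges_removed"] = current.number_of_edges() - filtered.number_of_edges()
        current = filtered
    if config.add_thres is not None:
        augmented = augment_edges(current, emb, config.add_thres)
        report["n_edges_added"] = augmented.number_of_edges() - current.number_of_edges()
        current = augmented
    report["n_edges_out"] = current.number_of_edges()
    return current, report
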