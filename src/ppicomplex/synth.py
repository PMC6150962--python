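"""Synthetic PPI networks with planted complexes.

The generator emulates the input regime of real PPI complex-detection studies:
a sparse undirected background graph (Erdos-Renyi, edge probability
``p_background``) in which a number of dense subgraphs — the planted complexes,
internal edge probability ``p_within`` — are embedded, optionally with extra
uniformly random noise edges and member overlap between complexes.  It also
fabricates an intermediate-quality complex set (planted complexes with a
fraction of members resampled), standing in for the output of an external
seed-and-extend predictor when building three-class training sets.

Background edges are drawn only between pairs that do not share a planted
complex, so the realized within-complex density is an unbiased estimate of
``p_within``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .ppi_io import Complex

__all__ = ["SynthConfig", "generate", "degrade_gold"]


@dataclass
class SynthConfig:
    """Parameters of the planted-complex generator.

    Defaults describe the standard fixture used throughout the test-bench:
    a 500-protein network with 20 planted complexes of 5-15 members, dense
    inside (0.8) and sparse outside (0.01).
    """

    n_background_nodes: int = 500
    n_complexes: int = 20
    size_min: int = 5
    size_max: int = 15
    p_within: float = 0.8
    p_background: float = 0.01
    noise_edge_fraction: float = 0.0
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_background < self.p_within <= 1.0):
            raise ValueError("require 0 <= p_background < p_within <= 1")
        if self.size_min < 3 or self.size_max < self.size_min:
            raise ValueError("require 3 <= size_min <= size_max")
        if not (0.0 <= self.noise_edge_fraction < 1.0):
            raise ValueError("noise_edge_fraction must be in [0,1)")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0,1]")
        if self.n_background_nodes < self.size_max:
            raise ValueError("size_max exceeds the node budget")


def _node_name(i: int) -> str:
    return f"P{i:04d}"


def generate(config: SynthConfig):
    """Generate ``(network, gold, intermediates)`` for a config.

    ``gold`` are the planted complexes (label ``positive``); ``intermediates``
    are the same complexes with 30% of members resampled (label
    ``intermediate``).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_background_nodes
    nodes = [_node_name(i) for i in range(n)]
    net = nx.Graph()
    net.add_nodes_from(nodes)

    sizes = rng.integers(config.size_min, config.size_max + 1,
                         size=config.n_complexes)
    unassigned = list(range(n))
    assigned: list = []
    memberships: list = []
    for size in sizes:
        members = []
        need = int(size)
        if assigned and rng.random() < config.overlap_fraction:
            members.append(int(rng.choice(assigned)))
            need -= 1
        if need > len(unassigned):
            raise ValueError(
                "node budget exhausted: cannot plant complexes of the "
                "requested sizes without more overlap or more nodes"
            )
        idx = rng.choice(len(unassigned), size=need, replace=False)
        picked = [unassigned[i] for i in sorted(idx, reverse=True)]
        for i in sorted(idx, reverse=True):
            del unassigned[i]
        members.extend(picked)
        assigned.extend(picked)
        memberships.append(sorted(members))

    # Planted internal edges.
    within_pairs = set()
    for members in memberships:
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                within_pairs.add((a, b) if a < b else (b, a))
    for a, b in sorted(within_pairs):
        if rng.random() < config.p_within:
            net.add_edge(nodes[a], nodes[b])

    # Background Erdos-Renyi over pairs not sharing a complex.
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < config.p_background
    for a, b in zip(iu[mask], ju[mask]):
        pair = (int(a), int(b))
        if pair not in within_pairs:
            net.add_edge(nodes[pair[0]], nodes[pair[1]])

    # Extra noise edges among current non-edges.
    n_noise = int(round(config.noise_edge_fraction * net.number_of_edges()))
    added = 0
    while added < n_noise:
        a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        u, v = nodes[int(a)], nodes[int(b)]
        if not net.has_edge(u, v):
            net.add_edge(u, v)
            added += 1

    gold = [Complex((nodes[i] for i in members), label="positive")
            for members in memberships]
    mid_seed = int(rng.integers(0, 2**31 - 1))
    intermediates = [
        Complex(cx.members, label="intermediate")
        for cx in degrade_gold(gold, 0.3, nodes, mid_seed)
    ]
    return net, gold, intermediates


def degrade_gold(gold, member_noise: float, nodes, seed: int):
    """Resample ``ceil(member_noise * size)`` members of each complex.

    Replacement members are drawn uniformly from ``nodes`` outside the
    complex; sizes are preserved.  ``member_noise=0`` is the identity.
    """
    if not (0.0 <= member_noise < 1.0):
        raise ValueError("member_noise must be in [0,1)")
    rng = np.random.default_rng(seed)
    nodes = sorted(nodes)
    out = []
    for cx in gold:
        members = sorted(cx.members)
        k = math.ceil(member_noise * len(members))
        if k == 0:
            out.append(Complex(members))
            continue
        drop_idx = rng.choice(len(members), size=k, replace=False)
        kept = {m for i, m in enumerate(members) if i not in set(drop_idx)}
        pool = [v for v in nodes if v not in cx.members]
        repl_idx = rng.choice(len(pool), size=k, replace=False)
        kept.update(pool[i] for i in repl_idx)
        out.append(Complex(kept))
    return out
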