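"""Supervised complex detection by regression-guided seed expansion (SLPC).

A three-class training set (known complexes as positives, predictions of an
intermediate-quality method as intermediates, random node sets as negatives)
is mapped to 11 topological features per induced subgraph and regressed onto
targets 1.0 / 0.5 / 0.0.  Every node whose degree exceeds the network's mean
degree seeds a search; seeds grow greedily by adding the adjacent node that
most increases the regression score, stopping when no addition improves the
score by more than ``tol`` or a size cap is reached.

The 11 features (computed on the subgraph induced by the complex members):
node count, edge count, density, mean / variance / maximum internal degree,
mean local clustering coefficient, fraction of members in the largest
connected component, mean external degree, internal-edge ratio
(internal / (internal + outgoing) edge endpoints), and mean internal edge
weight (1.0 on unweighted networks).  They span the density, connectivity and
separation axes standard in complex-quality scoring; the extractor is
pluggable if a different feature set is preferred.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .ppi_io import Complex

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "LabeledComplexSet",
    "TopoFeatureExtractor",
    "ComplexScorer",
    "topo_features",
    "sample_negative_subgraphs",
    "train_scorer",
    "select_seeds",
    "expand_seed",
    "detect_candidates",
]

FEATURE_NAMES = (
    "n_nodes",
    "n_edges",
    "density",
    "mean_internal_degree",
    "var_internal_degree",
    "max_internal_degree",
    "mean_clustering",
    "lcc_fraction",
    "mean_external_degree",
    "internal_edge_ratio",
    "mean_edge_weight",
)


@dataclass
class LabeledComplexSet:
    """Positive / intermediate / negative training complexes."""

    positives: List[Complex]
    intermediates: List[Complex]
    negatives: List[Complex]

    def validate(self) -> None:
        for name in ("positives", "intermediates", "negatives"):
            if not getattr(self, name):
                raise ValueError(f"training class {name!r} is empty")

    def labeled(self):
        for cx in self.positives:
            yield cx, "positive"
        for cx in self.intermediates:
            yield cx, "intermediate"
        for cx in self.negatives:
            yield cx, "negative"


class TopoFeatureExtractor:
    """Fast 11-feature extractor over induced subgraphs of one network.

    Precomputes adjacency sets once so repeated calls during seed expansion
    avoid networkx subgraph construction.
    """

    def __init__(self, net: nx.Graph):
        self.net = net
        self.adj = {v: set(net[v]) for v in net}
        self.weighted = any("weight" in d for _, _, d in net.edges(data=True))

    def __call__(self, members: Iterable[str]) -> np.ndarray:
        s = set(members)
        for v in s:
            if v not in self.adj:
                raise KeyError(f"complex member {v!r} not in network")
        n = len(s)
        nbrs_in = {v: self.adj[v] & s for v in s}
        int_deg = {v: len(nbrs_in[v]) for v in s}
        degs = np.array([int_deg[v] for v in sorted(s)], dtype=float)
        m = degs.sum() / 2.0

        density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0

        # Mean local clustering coefficient within the induced subgraph.
        clust = 0.0
        for v in s:
            kv = int_deg[v]
            if kv < 2:
                continue
            nb = sorted(nbrs_in[v])
            links = 0
            for i, a in enumerate(nb):
                links += sum(1 for b in nb[i + 1:] if b in nbrs_in[a])
            clust += 2.0 * links / (kv * (kv - 1))
        mean_clust = clust / n if n else 0.0

        # Largest connected component of the induced subgraph.
        seen: set = set()
        best = 0
        for v in s:
            if v in seen:
                continue
            stack, comp = [v], 0
            seen.add(v)
            while stack:
                x = stack.pop()
                comp += 1
                for y in nbrs_in[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            best = max(best, comp)
        lcc_frac = best / n if n else 0.0

        ext_deg = np.array([len(self.adj[v]) - int_deg[v] for v in sorted(s)],
                           dtype=float)
        total_ext = ext_deg.sum()
        denom = m + total_ext
        ratio = m / denom if denom > 0 else 0.0

        if m == 0:
            mean_w = 0.0
        elif not self.weighted:
            mean_w = 1.0
        else:
            wsum = 0.0
            for v in s:
                for x in nbrs_in[v]:
                    if v < x:
                        wsum += float(self.net[v][x].get("weight", 1.0))
            mean_w = wsum / m

        return np.array([
            float(n),
            m,
            density,
            degs.mean() if n else 0.0,
            degs.var() if n else 0.0,
            degs.max() if n else 0.0,
            mean_clust,
            lcc_frac,
            ext_deg.mean() if n else 0.0,
            ratio,
            mean_w,
        ])


def topo_features(cx: Complex, net: nx.Graph) -> np.ndarray:
    """The 11 topological features of ``cx``'s induced subgraph in ``net``."""
    return TopoFeatureExtractor(net)(cx.members)


@dataclass
class ComplexScorer:
    """A fitted regression scoring how complex-like an induced subgraph is.

    ``model`` is any object with a ``predict(X)`` method over 11-feature rows.
    ``max_positive_size`` feeds the default expansion size cap (twice the
    largest positive training complex).
    """

    model: object
    seed: int = 0
    model_family: str = "linear"
    train_r2: Optional[float] = None
    max_positive_size: Optional[int] = None

    def score(self, features: np.ndarray) -> float:
        return float(self.model.predict(np.asarray(features, dtype=float)[None, :])[0])

    def score_many(self, features: np.ndarray) -> np.ndarray:
        """Score a batch of feature rows in one model call."""
        return np.asarray(self.model.predict(np.asarray(features, dtype=float)),
                          dtype=float)

    def score_complex(self, cx: Complex, net: nx.Graph) -> float:
        return self.score(topo_features(cx, net))


def sample_negative_subgraphs(net: nx.Graph, size_pool: Sequence[int],
                              count: int, seed: int,
                              positives: Sequence[Complex] = ()) -> List[Complex]:
    """Uniformly random node sets as negative training samples.

    Sizes are drawn with replacement from ``size_pool``; any draw identical to
    a positive complex's member set is rejected and redrawn.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    nodes = sorted(net.nodes())
    for size in size_pool:
        if size < 2:
            raise ValueError("negative-sample sizes must be >= 2")
        if size > len(nodes):
            raise ValueError(f"requested size {size} exceeds |nodes|={len(nodes)}")
    rng = np.random.default_rng(seed)
    forbidden = {cx.members for cx in positives}
    out: List[Complex] = []
    while len(out) < count:
        size = int(size_pool[int(rng.integers(len(size_pool)))])
        idx = rng.choice(len(nodes), size=size, replace=False)
        members = frozenset(nodes[i] for i in idx)
        if members in forbidden:
            continue
        out.append(Complex(members, label="negative"))
    return out


def train_scorer(train: LabeledComplexSet, net: nx.Graph, seed: int = 0,
                 model: str = "quadratic",
                 model_factory: Optional[Callable[[], object]] = None) -> ComplexScorer:
    """Fit the regression scorer on a three-class training set.

    Targets: positive -> 1.0, intermediate -> 0.5, negative -> 0.0.  The
    default family is ridge regression over degree-2 polynomial features:
    greedy expansion needs a score that keeps rising from a small seed to a
    full-sized complex, which requires size-density interaction terms a
    purely linear fit cannot express (ordinary least squares on the raw
    features scores tiny cliques above full complexes and stalls expansion at
    triangles).  ``model="linear"`` selects plain least squares; pass
    ``model_factory`` for any other sklearn-style regressor.
    """
    train.validate()
    extractor = TopoFeatureExtractor(net)
    rows, targets = [], []
    target_of = {"positive": 1.0, "intermediate": 0.5, "negative": 0.0}
    for cx, label in train.labeled():
        if len(cx) < 2:
            raise ValueError("training complexes must have >=2 members")
        rows.append(extractor(cx.members))
        targets.append(target_of[label])
    x = np.stack(rows)
    y = np.array(targets)
    constant = [FEATURE_NAMES[i] for i in range(x.shape[1])
                if np.ptp(x[:, i]) == 0.0]
    if constant:
        warnings.warn(f"constant feature columns in training set: {constant}")
    if model_factory is not None:
        reg = model_factory()
        family = "custom"
    elif model == "quadratic":
        reg = make_pipeline(PolynomialFeatures(degree=2),
                            StandardScaler(), Ridge(alpha=1.0))
        family = "quadratic"
    elif model == "linear":
        reg = LinearRegression()
        family = "linear"
    else:
        raise ValueError(f"unknown model family: {model!r}")
    reg.fit(x, y)
    r2 = float(reg.score(x, y))
    logger.info("train_scorer: %s regression on %d samples, R^2=%.4f",
                family, len(y), r2)
    max_pos = max(len(cx) for cx in train.positives)
    return ComplexScorer(model=reg, seed=seed, model_family=family,
                         train_r2=r2, max_positive_size=max_pos)


def select_seeds(net: nx.Graph) -> List[Complex]:
    """Singleton seeds: every node with degree strictly above the mean degree."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    mean_deg = 2.0 * net.number_of_edges() / n
    seeds = [Complex([v]) for v in sorted(net.nodes())
             if net.degree(v) > mean_deg]
    if not seeds:
        warnings.warn("no node exceeds the mean degree; no seeds selected")
    return seeds


def expand_seed(seed: Complex, net: nx.Graph, scorer: ComplexScorer,
                max_size: int, tol: float = 1e-6,
                extractor: Optional[TopoFeatureExtractor] = None,
                grow_to: int = 1) -> Complex:
    """Greedily grow a seed by the neighbor giving the largest score increase.

    Stops when no adjacent node improves the score by more than ``tol`` or the
    size cap is hit.  Ties in score gain resolve to the lexicographically
    smallest node ID, making expansion deterministic.

    While the subgraph is smaller than ``grow_to`` the best-scoring neighbor
    is added regardless of improvement: regression scores on one- and
    two-node subgraphs are extrapolations far outside the training
    distribution, and an overshoot there would otherwise freeze the search
    below any reportable complex size.
    """
    if extractor is None:
        extractor = TopoFeatureExtractor(net)
    members = set(seed.members)
    current = scorer.score(extractor(members))
    while len(members) < max_size:
        frontier = set()
        for v in members:
            frontier |= extractor.adj[v]
        frontier -= members
        if not frontier:
            break
        candidates = sorted(frontier)
        feats = np.stack([extractor(members | {cand}) for cand in candidates])
        scores = scorer.score_many(feats)
        best_idx = int(np.argmax(scores))  # argmax keeps the first (smallest ID) tie
        best_node, best_score = candidates[best_idx], float(scores[best_idx])
        if best_score - current > tol or len(members) < grow_to:
            members.add(best_node)
            current = best_score
        else:
            break
    return Complex(members, score=current)


def detect_candidates(net: nx.Graph, scorer: ComplexScorer, min_size: int = 3,
                      max_size: Optional[int] = None,
                      tol: float = 1e-6) -> List[Complex]:
    """Expand every above-average-degree seed into a candidate complex.

    Candidates smaller than ``min_size`` and exact duplicate member sets are
    dropped.  ``max_size`` defaults to twice the largest positive complex seen
    in training.
    """
    if max_size is None:
        if scorer.max_positive_size is None:
            raise ValueError("max_size not given and scorer lacks training metadata")
        max_size = 2 * scorer.max_positive_size
    seeds = select_seeds(net)
    if not seeds:
        warnings.warn("no seeds: returning no candidates")
        return []
    extractor = TopoFeatureExtractor(net)
    seen: set = set()
    out: List[Complex] = []
    for seed in seeds:
        cx = expand_seed(seed, net, scorer, max_size=max_size, tol=tol,
                         extractor=extractor, grow_to=min_size)
        if len(cx) < min_size or cx.members in seen:
            continue
        seen.add(cx.members)
        out.append(cx)
    logger.info("detect_candidates: %d seeds -> %d candidates", len(seeds), len(out))
    return out
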