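"""Topological features, scorer training, seed selection and expansion."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from ppicomplex import (Complex, FEATURE_NAMES, LabeledComplexSet,
                        SynthConfig, detect_candidates, expand_seed, generate,
                        sample_negative_subgraphs, select_seeds, topo_features,
                        train_scorer)
from ppicomplex.pipeline import PipelineConfig, run_pipeline
from ppicomplex.slpc import ComplexScorer

from conftest import random_graph


class DensityScorer(ComplexScorer):
    """A clique-favoring scorer: density + mean internal degree."""

    def __init__(self):
        class _M:
            def predict(self, x):
                x = np.atleast_2d(x)
                return x[:, 2] + 0.1 * x[:, 3]
        super().__init__(model=_M(), model_family="custom", max_positive_size=10)


class TestTopoFeatures:
    def test_triangle_is_perfect_clique(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        f = dict(zip(FEATURE_NAMES, topo_features(Complex({"a", "b", "c"}), net)))
        assert f["density"] == 1.0
        assert f["mean_clustering"] == 1.0
        assert f["lcc_fraction"] == 1.0
        assert f["n_edges"] == 3.0

    def test_edgeless_induced_subgraph(self):
        net = nx.Graph([("a", "x"), ("b", "x"), ("c", "x")])
        f = dict(zip(FEATURE_NAMES, topo_features(Complex({"a", "b", "c"}), net)))
        assert f["density"] == 0.0
        assert f["mean_internal_degree"] == 0.0
        assert f["lcc_fraction"] == pytest.approx(1 / 3)
        assert f["mean_external_degree"] == 1.0
        assert f["mean_edge_weight"] == 0.0

    def test_all_features_match_networkx_recomputation(self):
        """Independent recomputation of all 11 features via networkx."""
        net = random_graph(25, 0.25, seed=3)
        rng = np.random.default_rng(1)
        for _ in range(10):
            members = set(rng.choice(sorted(net.nodes()), 6, replace=False))
            feats = dict(zip(FEATURE_NAMES,
                             topo_features(Complex(members), net)))
            sub = net.subgraph(members)
            degs = [d for _, d in sub.degree()]
            assert feats["n_nodes"] == 6
            assert feats["n_edges"] == sub.number_of_edges()
            assert feats["density"] == pytest.approx(nx.density(sub))
            assert feats["mean_internal_degree"] == pytest.approx(np.mean(degs))
            assert feats["var_internal_degree"] == pytest.approx(np.var(degs))
            assert feats["max_internal_degree"] == max(degs)
            assert feats["mean_clustering"] == pytest.approx(
                np.mean(list(nx.clustering(sub).values())))
            lcc = max(nx.connected_components(sub), key=len)
            assert feats["lcc_fraction"] == pytest.approx(len(lcc) / 6)
            ext = np.mean([net.degree(v) - sub.degree(v) for v in members])
            assert feats["mean_external_degree"] == pytest.approx(ext)
            boundary = sum(net.degree(v) - sub.degree(v) for v in members)
            expected_ratio = (sub.number_of_edges() /
                              (sub.number_of_edges() + boundary)
                              if sub.number_of_edges() + boundary else 0.0)
            assert feats["internal_edge_ratio"] == pytest.approx(expected_ratio)
            assert feats["mean_edge_weight"] == (1.0 if sub.number_of_edges()
                                                 else 0.0)

    def test_weighted_mean_edge_weight(self):
        net = nx.Graph()
        net.add_edge("a", "b", weight=0.2)
        net.add_edge("b", "c", weight=0.8)
        f = dict(zip(FEATURE_NAMES, topo_features(Complex({"a", "b", "c"}), net)))
        assert f["mean_edge_weight"] == pytest.approx(0.5)

    def test_member_outside_network_error(self):
        net = nx.Graph([("a", "b")])
        with pytest.raises(KeyError):
            topo_features(Complex({"a", "ghost"}), net)


class TestSampleNegatives:
    def test_zero_count(self):
        net = random_graph(10, 0.3, seed=1)
        assert sample_negative_subgraphs(net, [3], 0, seed=0) == []

    def test_reproducible_and_distinct_from_positives(self):
        net = random_graph(10, 0.5, seed=2)
        pos = [Complex(set(sorted(net.nodes())[:3]))]
        a = sample_negative_subgraphs(net, [3], 5, seed=7, positives=pos)
        b = sample_negative_subgraphs(net, [3], 5, seed=7, positives=pos)
        assert [c.members for c in a] == [c.members for c in b]
        assert all(c.members != pos[0].members for c in a)
        assert all(len(c) == 3 for c in a)

    def test_size_exceeding_nodes_error(self):
        net = random_graph(5, 0.5, seed=3)
        with pytest.raises(ValueError):
            sample_negative_subgraphs(net, [6], 1, seed=0)

    def test_uniform_over_3_subsets_of_k5(self):
        net = nx.relabel_nodes(nx.complete_graph(5), str)
        draws = sample_negative_subgraphs(net, [3], 10_000, seed=5)
        counts = {}
        for cx in draws:
            counts[cx.members] = counts.get(cx.members, 0) + 1
        n_subsets = math.comb(5, 3)
        assert len(counts) == n_subsets
        p = 1 / n_subsets
        sigma = math.sqrt(10_000 * p * (1 - p))
        for c in counts.values():
            assert abs(c - 10_000 * p) < 3 * sigma


class TestTrainScorer:
    def _net_three_densities(self):
        # components: a 5-clique, a 5-node cycle (density 0.5), 5 isolated
        net = nx.Graph()
        clique = [f"p{i}" for i in range(5)]
        net.add_edges_from(itertools.combinations(clique, 2))
        cyc = [f"m{i}" for i in range(5)]
        nx.add_cycle(net, cyc)
        net.add_nodes_from(f"n{i}" for i in range(5))
        return net, clique, cyc, [f"n{i}" for i in range(5)]

    def test_separates_cliques_from_edgeless(self):
        net, clique, cyc, empty = self._net_three_densities()
        train = LabeledComplexSet([Complex(clique, label="positive")],
                                  [Complex(cyc, label="intermediate")],
                                  [Complex(empty, label="negative")])
        scorer = train_scorer(train, net, seed=0)
        assert scorer.score_complex(Complex(clique), net) > \
            scorer.score_complex(Complex(empty), net)

    def test_perfectly_correlated_feature_r2(self):
        """Density tracks the target exactly (1 / 0.5 / 0) -> R^2 ~ 1."""
        net, clique, cyc, empty = self._net_three_densities()
        train = LabeledComplexSet([Complex(clique, label="positive")] * 3,
                                  [Complex(cyc, label="intermediate")] * 3,
                                  [Complex(empty, label="negative")] * 3)
        scorer = train_scorer(train, net, seed=0, model="linear")
        assert scorer.train_r2 >= 0.99

    def test_deterministic_predictions(self):
        net, clique, cyc, empty = self._net_three_densities()
        train = LabeledComplexSet([Complex(clique, label="positive")],
                                  [Complex(cyc, label="intermediate")],
                                  [Complex(empty, label="negative")])
        s1 = train_scorer(train, net, seed=3)
        s2 = train_scorer(train, net, seed=3)
        probe = topo_features(Complex(cyc), net)
        assert s1.score(probe) == s2.score(probe)

    def test_missing_class_rejected(self):
        net, clique, cyc, _ = self._net_three_densities()
        bad = LabeledComplexSet([Complex(clique, label="positive")],
                                [Complex(cyc, label="intermediate")], [])
        with pytest.raises(ValueError, match="negatives"):
            train_scorer(bad, net)


class TestSelectSeeds:
    def test_star_hub_only(self):
        net = nx.Graph([("h", "a"), ("h", "b"), ("h", "c")])
        seeds = select_seeds(net)
        assert [set(s.members) for s in seeds] == [{"h"}]

    def test_path_middle_node(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        assert [set(s.members) for s in select_seeds(net)] == [{"b"}]

    def test_regular_graph_no_seeds(self):
        net = nx.relabel_nodes(nx.cycle_graph(6), str)
        with pytest.warns(UserWarning, match="no seeds"):
            assert select_seeds(net) == []


class TestExpandSeed:
    def test_recovers_planted_clique(self):
        net = nx.relabel_nodes(nx.complete_graph(6), lambda i: f"c{i}")
        tail = nx.relabel_nodes(nx.path_graph(4), lambda i: f"t{i}")
        net = nx.union(net, tail)
        net.add_edge("c0", "t0")
        result = expand_seed(Complex({"c1"}), net, DensityScorer(), max_size=10)
        assert {f"c{i}" for i in range(6)} <= set(result.members)
        assert not {f"t{i}" for i in range(1, 4)} & set(result.members)

    def test_isolated_seed_unchanged(self):
        net = nx.Graph([("a", "b")])
        net.add_node("z")
        result = expand_seed(Complex({"z"}), net, DensityScorer(), max_size=5)
        assert set(result.members) == {"z"}

    def test_max_size_equal_seed_unchanged(self):
        net = nx.relabel_nodes(nx.complete_graph(5), str)
        result = expand_seed(Complex({"0"}), net, DensityScorer(), max_size=1)
        assert set(result.members) == {"0"}

    def test_result_connected_and_contains_seed(self):
        for seed in range(5):
            net = random_graph(30, 0.15, seed=seed)
            scorer = DensityScorer()
            start = sorted(net.nodes())[seed]
            result = expand_seed(Complex({start}), net, scorer, max_size=12,
                                 grow_to=3)
            assert start in result.members
            sub = net.subgraph(result.members)
            if len(result) > 1 and net.degree(start) > 0:
                assert nx.is_connected(sub)


class TestDetectCandidates:
    def test_two_disjoint_cliques_found(self):
        net = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        net = nx.relabel_nodes(net, {i: f"N{i:02d}" for i in net.nodes()})
        # a sparse tail keeps the clique nodes above mean degree
        nx.add_path(net, ["N00", "X0", "X1", "X2", "X3", "X4", "X5"])
        cands = detect_candidates(net, DensityScorer(), min_size=3, max_size=8)
        found = {frozenset(c.members) for c in cands}
        assert frozenset(f"N{i:02d}" for i in range(6)) in found
        assert frozenset(f"N{i:02d}" for i in range(6, 12)) in found

    def test_empty_graph(self):
        net = nx.Graph()
        net.add_nodes_from("abc")
        with pytest.warns(UserWarning):
            assert detect_candidates(net, DensityScorer(), max_size=5) == []

    def test_duplicate_expansions_deduplicated(self):
        net = nx.relabel_nodes(nx.complete_graph(6), lambda i: f"c{i}")
        net.add_edge("c0", "x")  # make degrees unequal so seeds exist
        cands = detect_candidates(net, DensityScorer(), min_size=3, max_size=6)
        members = [c.members for c in cands]
        assert len(members) == len(set(members))

    def test_deterministic(self):
        net = random_graph(40, 0.15, seed=9)
        scorer = DensityScorer()
        a = detect_candidates(net, scorer, min_size=3, max_size=8)
        b = detect_candidates(net, scorer, min_size=3, max_size=8)
        assert [c.members for c in a] == [c.members for c in b]

    def test_scores_attached(self):
        net = random_graph(30, 0.2, seed=10)
        for cx in detect_candidates(net, DensityScorer(), min_size=3, max_size=6):
            assert cx.score is not None


def test_half_training_recovery():
    """Training on half the planted complexes still recovers the full set
    (F >= 0.5 at NA >= 0.25)."""
    net, gold, mid = generate(SynthConfig(n_background_nodes=300,
                                          n_complexes=12, size_min=5,
                                          size_max=10, seed=42))
    half, half_mid = gold[::2], mid[::2]
    result = run_pipeline(net, half, intermediates=half_mid, gold=gold,
                          config=PipelineConfig(seed=0))
    assert result.f_score >= 0.5
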