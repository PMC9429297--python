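import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from carenet import metrics as M
from carenet.metrics import (
    Aggregation,
    DEFAULT_CONFIG,
    MetricConfig,
    PathMode,
    Projection,
    UndefinedMetricError,
    UnreachablePolicy,
)
from conftest import complete, make_network, random_digraph, random_linked_digraph, star

EXCLUDE_SELF = dataclasses.replace(DEFAULT_CONFIG, path_mode=PathMode.EXCLUDE_SELF_PAIRS)
MEAN_CFG = dataclasses.replace(
    DEFAULT_CONFIG, centrality_aggregation=Aggregation.MEAN_NORMALIZED
)
DIRECTED_CFG = dataclasses.replace(DEFAULT_CONFIG, projection=Projection.DIRECTED)


class TestDensity:
    def test_formula(self, rng):
        net = random_digraph(rng, 5, 0.0)
        net = make_network(net.nodes, [("v00", "v01"), ("v00", "v02"), ("v00", "v03"),
                                       ("v01", "v00"), ("v01", "v02"), ("v02", "v03"),
                                       ("v03", "v00"), ("v04", "v00")])
        assert M.density(net) == pytest.approx(0.4)

    def test_complete(self):
        assert M.density(complete(4)) == 1.0

    def test_too_small(self):
        with pytest.raises(UndefinedMetricError):
            M.density(make_network("a", []))


class TestDiameter:
    def test_path4(self, path4):
        assert M.diameter(path4) == 3

    def test_star5(self):
        assert M.diameter(star(5)) == 2

    def test_no_links(self):
        with pytest.raises(UndefinedMetricError):
            M.diameter(make_network("abc", []))

    def test_largest_component_only(self):
        # two components: a-b-c path and isolated d-e link
        net = make_network("abcde", [("a", "b"), ("b", "c"), ("d", "e")])
        assert M.diameter(net) == 2


class TestPathLength:
    def test_triangle_include_self(self, triangle):
        assert M.path_length(triangle) == pytest.approx(6 / 9)

    def test_triangle_exclude_self(self, triangle):
        assert M.path_length(triangle, EXCLUDE_SELF) == pytest.approx(1.0)

    def test_star4_include_self(self):
        assert M.path_length(star(4)) == pytest.approx(18 / 16)

    def test_no_links(self):
        with pytest.raises(UndefinedMetricError):
            M.path_length(make_network("ab", []))


class TestClustering:
    def test_triangle(self, triangle):
        assert M.clustering_coefficient(triangle) == 1.0

    def test_star5(self):
        assert M.clustering_coefficient(star(5)) == 0.0

    def test_too_small(self):
        with pytest.raises(UndefinedMetricError):
            M.clustering_coefficient(make_network("ab", [("a", "b")]))


class TestAssortativity:
    def test_star4(self):
        assert M.assortativity(star(4)) == pytest.approx(-1.0)

    def test_cycle_undefined(self):
        net = make_network("abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        with pytest.raises(UndefinedMetricError):
            M.assortativity(net)

    def test_no_links(self):
        with pytest.raises(UndefinedMetricError):
            M.assortativity(make_network("ab", []))


class TestReciprocity:
    def test_two_of_three(self):
        net = make_network("abc", [("a", "b"), ("b", "a"), ("a", "c")])
        assert M.reciprocity(net) == pytest.approx(2 / 3)

    def test_symmetric(self):
        assert M.reciprocity(complete(4)) == 1.0

    def test_dag(self):
        net = make_network("abcd", [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")])
        assert M.reciprocity(net) == 0.0


class TestCentralityScores:
    def test_star_extremes(self):
        for n in (3, 7, 11):
            s = star(n)
            assert M.degree_score(s) == pytest.approx(1.0)
            assert M.closeness_score(s) == pytest.approx(1.0)
            assert M.betweenness_score(s) == pytest.approx(1.0)

    def test_complete_extremes(self):
        for n in (3, 8, 30):
            c = complete(n)
            assert M.degree_score(c) == 0.0
            assert M.closeness_score(c) == 0.0
            assert M.betweenness_score(c) == 0.0

    def test_path4_derived_values(self, path4):
        assert M.degree_score(path4) == pytest.approx(1 / 3)
        assert M.betweenness_score(path4) == pytest.approx(4 / 9)
        assert M.closeness_score(path4) == pytest.approx(0.5 / 1.2)

    def test_mean_normalized_degree_matches_undirected_density(self):
        # mean of deg/(n-1) equals undirected edge density
        net = make_network("abcd", [("a", "b"), ("c", "d"), ("b", "c")])
        assert M.degree_score(net, MEAN_CFG) == pytest.approx(2 * 3 / (4 * 3))

    def test_mean_normalized_star(self):
        n = 5
        expected = (1 * (n - 1) / (n - 1) + (n - 1) * 1 / (n - 1)) / n
        assert M.degree_score(star(n), MEAN_CFG) == pytest.approx(expected)

    def test_too_small(self):
        with pytest.raises(UndefinedMetricError):
            M.degree_score(make_network("ab", [("a", "b")]))


class TestComputeAll:
    def test_complete_digraph(self):
        rec = M.compute_all(complete(10))
        assert rec.density == 1.0
        assert rec.reciprocity == 1.0
        assert rec.clustering == 1.0
        assert rec.degree_score == 0.0
        assert rec.closeness_score == 0.0
        assert rec.betweenness_score == 0.0
        assert rec.assortativity is None
        assert "assortativity" in rec.undefined

    def test_star_digraph(self):
        rec = M.compute_all(star(11))
        assert rec.degree_score == pytest.approx(1.0)
        assert rec.closeness_score == pytest.approx(1.0)
        assert rec.betweenness_score == pytest.approx(1.0)
        assert rec.assortativity == pytest.approx(-1.0)

    def test_no_links_all_flagged(self):
        rec = M.compute_all(make_network("abcdefghij", []))
        assert rec.n_nodes == 10
        assert rec.density == 0.0
        for f in ("diameter", "path_length", "assortativity", "reciprocity",
                  "closeness_score", "betweenness_score"):
            assert getattr(rec, f) is None
            assert f in rec.undefined

    def test_oracle_twins_on_random_digraphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            p = float(rng.uniform(0.1, 0.9))
            net = random_linked_digraph(rng, n, p)
            rec = M.compute_all(net)
            assert rec.density == pytest.approx(oracles.oracle_density(net), abs=1e-9)
            assert rec.diameter == pytest.approx(oracles.oracle_diameter(net), abs=1e-9)
            assert rec.path_length == pytest.approx(oracles.oracle_path_length(net), abs=1e-9)
            assert rec.clustering == pytest.approx(oracles.oracle_clustering(net), abs=1e-9)
            assert rec.reciprocity == pytest.approx(oracles.oracle_reciprocity(net), abs=1e-9)
            ora = oracles.oracle_assortativity(net)
            if ora is None:
                assert rec.assortativity is None
            else:
                assert rec.assortativity == pytest.approx(ora, abs=1e-9)
            assert rec.degree_score == pytest.approx(oracles.oracle_degree_score(net), abs=1e-9)
            assert rec.closeness_score == pytest.approx(
                oracles.oracle_closeness_score(net), abs=1e-9
            )
            assert rec.betweenness_score == pytest.approx(
                oracles.oracle_betweenness_score(net), abs=1e-9
            )


class TestInvariants:
    @settings(max_examples=40, deadline=None)
    @given(n=st.integers(3, 14), p=st.floats(0.05, 0.95), seed=st.integers(0, 10**6))
    def test_bounds(self, n, p, seed):
        net = random_linked_digraph(np.random.default_rng(seed), n, p)
        rec = M.compute_all(net)
        for f in ("density", "clustering", "reciprocity", "degree_score",
                  "closeness_score", "betweenness_score"):
            v = getattr(rec, f)
            if v is not None:
                assert 0.0 <= v <= 1.0, f
        if rec.assortativity is not None:
            assert -1.0 - 1e-9 <= rec.assortativity <= 1.0 + 1e-9
        if rec.diameter is not None:
            assert rec.diameter >= 1

    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(3, 10), p=st.floats(0.1, 0.9), seed=st.integers(0, 10**6))
    def test_label_invariance(self, n, p, seed):
        rng = np.random.default_rng(seed)
        net = random_linked_digraph(rng, n, p)
        nodes = sorted(net.nodes)
        perm = dict(zip(nodes, rng.permutation([f"z{i}" for i in range(n)])))
        permuted = make_network(
            [perm[u] for u in nodes], [(perm[u], perm[v]) for u, v in net.links]
        )
        r1, r2 = M.compute_all(net), M.compute_all(permuted)
        for f in ("density", "diameter", "path_length", "clustering", "reciprocity",
                  "assortativity", "degree_score", "closeness_score", "betweenness_score"):
            v1, v2 = getattr(r1, f), getattr(r2, f)
            if v1 is None:
                assert v2 is None
            else:
                assert v1 == pytest.approx(v2, abs=1e-12), f

    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(3, 10), p=st.floats(0.2, 0.8), seed=st.integers(0, 10**6))
    def test_projection_consistency_on_symmetric_digraphs(self, n, p, seed):
        rng = np.random.default_rng(seed)
        base = random_linked_digraph(rng, n, p)
        sym = make_network(
            base.nodes, list(base.links) + [(v, u) for u, v in base.links]
        )
        for fn in (M.diameter, M.path_length, M.closeness_score, M.betweenness_score):
            try:
                undirected_value = fn(sym, DEFAULT_CONFIG)
            except UndefinedMetricError:
                with pytest.raises(UndefinedMetricError):
                    fn(sym, DIRECTED_CFG)
                continue
            assert undirected_value == pytest.approx(
                fn(sym, DIRECTED_CFG), abs=1e-9
            ), fn.__name__


class TestPolicies:
    def test_reachable_pairs_only_path_length(self):
        # two components: path a-b and isolated c
        net = make_network("abc", [("a", "b")])
        cfg = dataclasses.replace(
            EXCLUDE_SELF, unreachable_policy=UnreachablePolicy.REACHABLE_PAIRS_ONLY
        )
        assert M.path_length(net, cfg) == pytest.approx(1.0)

    def test_density_counts_isolated_nodes(self):
        net = make_network("abcde", [("a", "b")])
        assert M.density(net) == pytest.approx(1 / 20)

    def test_degree_score_counts_isolated_nodes(self):
        # star on 4 plus an isolated 5th node: centralization drops below 1
        s = star(4)
        with_iso = make_network(list(s.nodes) + ["iso"], s.links)
        assert M.degree_score(with_iso) < 1.0
        assert M.degree_score(s) == pytest.approx(1.0)
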