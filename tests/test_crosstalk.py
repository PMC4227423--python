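"""Hypergeometric pathway-pathway interaction statistic and network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crosspath import (
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
    build_pathway_network,
    count_pair_interactions,
    pathway_interaction_p,
)
from oracles import hypergeom_tail_by_subsets, hypergeom_tail_oracle


class TestCountPairInteractions:
    def test_three_edge_hand_enumeration(self):
        network = InteractionNetwork([("a", "x"), ("b", "y"), ("a", "b")])
        N, M, n, k = count_pair_interactions(network, {"a", "b"}, {"a"}, {"b"})
        assert (N, M, n, k) == (3, 2, 2, 1)

    def test_disjoint_pathways_without_cross_edges(self):
        network = InteractionNetwork([("a", "b"), ("c", "d")])
        *_, k = count_pair_interactions(network, {"a", "c"}, {"a", "b"}, {"c", "d"})
        assert k == 0

    def test_saturation_when_both_sets_cover_everything(self):
        network = InteractionNetwork([("a", "b"), ("b", "c"), ("c", "d")])
        genes = {"a", "b", "c", "d"}
        N, M, n, k = count_pair_interactions(network, genes, genes, genes)
        assert N == M == n == k == 3

    def test_non_deg_edges_never_counted(self):
        network = InteractionNetwork([("a", "b"), ("x", "y")])
        N, M, n, k = count_pair_interactions(
            network, {"a"}, {"a", "x"}, {"b", "y"})
        assert N == 1 and M == 1 and n == 1 and k == 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            count_pair_interactions(InteractionNetwork(), {"a"}, {"a"}, {"b"})


class TestPathwayInteractionP:
    def test_zero_observed_gives_one(self):
        assert pathway_interaction_p(100, 30, 20, 0) == 1.0

    def test_direct_combinatorial_example(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert pathway_interaction_p(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_exact_enumeration_all_small_instances(self):
        for N in range(1, 13):
            for M in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(M, n) + 1):
                        p = pathway_interaction_p(N, M, n, k)
                        expected = hypergeom_tail_oracle(k, N, M, n)
                        assert p == pytest.approx(expected, rel=1e-10, abs=1e-15)

    def test_subset_enumeration_oracle(self):
        # brute force over all n-subsets of the N interactions
        rng = np.random.default_rng(0)
        for _ in range(25):
            N = int(rng.integers(2, 13))
            M = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(M, n) + 1))
            p = pathway_interaction_p(N, M, n, k)
            assert p == pytest.approx(
                hypergeom_tail_by_subsets(k, N, M, n), rel=1e-10, abs=1e-15)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            N = int(rng.integers(50, 500))
            M = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(1, min(M, n) + 1))
            p = pathway_interaction_p(N, M, n, k)
            draws = rng.hypergeometric(M, N - M, n, size=200_000)
            freq = float((draws >= k).mean())
            se = max(np.sqrt(p * (1 - p) / draws.size), 1e-6)
            assert abs(freq - p) <= 4 * se

    @given(st.integers(1, 60), st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_non_increasing_in_k_and_symmetric(self, N, data):
        M = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        values = [pathway_interaction_p(N, M, n, k) for k in range(min(M, n) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        for k in range(min(M, n) + 1):
            assert pathway_interaction_p(N, M, n, k) == pytest.approx(
                pathway_interaction_p(N, n, M, k), rel=1e-12)

    def test_invalid_counts_named_in_errors(self):
        with pytest.raises(ValueError, match="M=11 exceeds N=10"):
            pathway_interaction_p(10, 11, 4, 1)
        with pytest.raises(ValueError, match="n=12 exceeds N=10"):
            pathway_interaction_p(10, 5, 12, 1)
        with pytest.raises(ValueError, match="k_obs=5"):
            pathway_interaction_p(10, 5, 4, 5)
        with pytest.raises(ValueError, match="N must be non-negative"):
            pathway_interaction_p(-1, 0, 0, 0)


def _planted_toy():
    """Three pathways; (1,2) densely cross-connected, pathway 3 isolated."""
    p1 = [f"a{i}" for i in range(4)]
    p2 = [f"b{i}" for i in range(4)]
    p3 = [f"c{i}" for i in range(4)]
    cross = [(p1[i], p2[j]) for i, j in
             [(0, 0), (0, 1), (1, 1), (1, 2), (2, 2), (2, 3), (3, 3), (3, 0)]]
    background = [(f"z{i}", f"z{i+1}") for i in range(20)]
    degs = set(p1 + p2 + p3 + [f"z{i}" for i in range(21)])
    network = InteractionNetwork(cross + background)
    sets = GeneSetCollection([
        GeneSet("path1", "", frozenset(p1)),
        GeneSet("path2", "", frozenset(p2)),
        GeneSet("path3", "", frozenset(p3)),
    ])
    return network, degs, sets


class TestBuildPathwayNetwork:
    def test_planted_toy_recovers_exactly_the_dense_pair(self):
        network, degs, sets = _planted_toy()
        result = build_pathway_network(network, degs, sets, threshold=0.05)
        assert result.network.edges() == [("path1", "path2")]
        pair = result.pairs.set_index(["pathway_1", "pathway_2"]).loc[
            ("path1", "path2")]
        # hand enumeration: 28 DEG edges total, 8 touch path1, 8 touch path2,
        # all 8 cross
        assert (pair["N"], pair["M"], pair["n"], pair["k"]) == (28, 8, 8, 8)
        assert result.has_interactions

    def test_disconnected_pathways_report_no_interactions(self):
        network = InteractionNetwork([("a", "b"), ("c", "d")])
        sets = GeneSetCollection([
            GeneSet("p1", "", frozenset(["a", "b"])),
            GeneSet("p2", "", frozenset(["c", "d"])),
        ])
        result = build_pathway_network(network, {"a", "c"}, sets, threshold=0.05)
        assert not result.has_interactions
        assert result.describe() == "no interactions"
        assert result.network.n_nodes == 2  # nodes kept even with no edges

    def test_matches_per_pair_recomputation(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:03d}" for i in range(60)]
        edges = set()
        while len(edges) < 150:
            u, v = rng.choice(60, 2, replace=False)
            edges.add(tuple(sorted((genes[u], genes[v]))))
        network = InteractionNetwork(edges)
        degs = set(rng.choice(genes, 25, replace=False))
        sets = GeneSetCollection([
            GeneSet(f"p{j}", "", frozenset(rng.choice(genes, 12, replace=False)))
            for j in range(5)
        ])
        result = build_pathway_network(network, degs, sets, threshold=0.1)
        expected_edges = []
        for row in result.pairs.itertuples(index=False):
            s1 = sets[row.pathway_1].members
            s2 = sets[row.pathway_2].members
            N, M, n, k = count_pair_interactions(network, degs, s1, s2)
            assert (row.N, row.M, row.n, row.k) == (N, M, n, k)
            p = hypergeom_tail_oracle(k, N, M, n)
            assert row.p == pytest.approx(p, rel=1e-10)
            if p < 0.1:
                expected_edges.append(tuple(sorted((row.pathway_1, row.pathway_2))))
        assert result.network.edges() == sorted(expected_edges)

    def test_fewer_than_two_sets_rejected(self):
        network = InteractionNetwork([("a", "b")])
        sets = GeneSetCollection([GeneSet("p1", "", frozenset(["a"]))])
        with pytest.raises(ValueError, match="at least 2"):
            build_pathway_network(network, {"a"}, sets)

    def test_pair_stats_symmetric_in_set_order(self):
        network, degs, sets = _planted_toy()
        N1, M1, n1, k1 = count_pair_interactions(
            network, degs, sets["path1"].members, sets["path2"].members)
        N2, M2, n2, k2 = count_pair_interactions(
            network, degs, sets["path2"].members, sets["path1"].members)
        assert (N1, M1, n1, k1) == (N2, n2, M2, k2)
        assert pathway_interaction_p(N1, M1, n1, k1) == pytest.approx(
            pathway_interaction_p(N2, M2, n2, k2))
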