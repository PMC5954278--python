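"""Edge test, network assembly, statistics, sweep and ego extraction."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lncnet.expression import ExpressionMatrix
from lncnet.network import (
    EdgeTestError,
    build_network,
    classify_edges,
    clustering_coefficient,
    edge_category_fractions,
    ego_subnetwork,
    network_stats,
    network_sweep,
    read_edge_list,
    spearman_edge_test,
    transitivity,
    write_edge_list,
)
from lncnet.synthetic import generate_expression, SyntheticConfig


def brute_force_c_t(g: nx.Graph):
    """O(n^3) triangle/triple enumeration, independent of the implementation."""
    nodes = list(g.nodes)
    tri_at = {v: 0 for v in nodes}
    for a, b, c in itertools.combinations(nodes, 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            tri_at[a] += 1
            tri_at[b] += 1
            tri_at[c] += 1
    per_node = {}
    for v in nodes:
        d = g.degree(v)
        per_node[v] = 0.0 if d < 2 else tri_at[v] / (d * (d - 1) / 2)
    c = sum(per_node.values()) / len(nodes) if nodes else 0.0
    triples = sum(g.degree(v) * (g.degree(v) - 1) / 2 for v in nodes)
    triangles = sum(tri_at.values()) / 3
    t = 0.0 if triples == 0 else 3 * triangles / triples
    return c, per_node, t


class TestSpearmanEdgeTest:
    def test_perfect_monotone(self):
        rs, z, p = spearman_edge_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert rs == pytest.approx(1.0)
        assert p < 1e-10

    def test_antitone(self):
        rs, _, _ = spearman_edge_test([1, 2, 3, 4], [4, 3, 2, 1])
        assert rs == pytest.approx(-1.0)

    def test_hand_computed_pair_and_permutation_p(self):
        # ranks of y = (2,1,4,3,5); rank-Pearson by hand: Rs = 8/10 = 0.8
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        rs, z, p = spearman_edge_test(x, y)
        assert rs == pytest.approx(0.8)
        # exact permutation null of |Rs| over all 120 orderings of y
        obs = abs(rs)
        count = 0
        for perm in itertools.permutations(y):
            r, _, _ = spearman_edge_test(x, list(perm))
            if abs(r) >= obs - 1e-12:
                count += 1
        p_perm = count / math.factorial(5)
        assert abs(p - p_perm) < 0.06

    def test_constant_vector_rejected(self):
        with pytest.raises(EdgeTestError, match="constant"):
            spearman_edge_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(EdgeTestError):
            spearman_edge_test([1, 2, 3], [3, 2, 1])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 12))
    def test_symmetry_and_rank_invariance(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        fwd = spearman_edge_test(x, y)
        rev = spearman_edge_test(y, x)
        assert fwd == pytest.approx(rev)
        # strictly increasing transforms leave ranks, hence Rs, unchanged
        warped = spearman_edge_test(np.exp(x), y)
        assert warped[0] == pytest.approx(fwd[0])
        cubed = spearman_edge_test(x, y**3 if (y > 0).all() else np.exp(y))
        assert cubed[0] == pytest.approx(fwd[0])


class TestBuildNetwork:
    def test_three_gene_oracle(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=20)
        values = pd.DataFrame(
            [base + rng.normal(scale=0.05, size=20) + 10,
             base + rng.normal(scale=0.05, size=20) + 10,
             rng.normal(size=20) + 10],
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(20)],
        ).abs()
        m = ExpressionMatrix(
            values, pd.Series({"a": "coding", "b": "coding", "c": "lncRNA"})
        )
        net = build_network(m, rho_cutoff=0.5, alpha=0.01)
        # oracle: all-pairs edge test plus the per-gene Bonferroni rule
        expected = set()
        for ga, gb in itertools.combinations(["a", "b", "c"], 2):
            rs, _, p = spearman_edge_test(values.loc[ga], values.loc[gb])
            p_adj = min(1.0, p * 2)  # each gene participates in 2 tests
            if rs >= 0.5 and p_adj <= 0.01:
                expected.add((ga, gb))
        assert set(map(tuple, map(sorted, net.edges))) == expected == {("a", "b")}
        assert net.edges["a", "b"]["p_adj"] == pytest.approx(
            min(1.0, 2 * spearman_edge_test(values.loc["a"], values.loc["b"])[2])
        )

    def test_noise_free_modules_are_cliques(self, noise_free_dataset):
        matrix, truth = noise_free_dataset
        net = build_network(matrix, 0.5, 0.01)
        for a, b in itertools.combinations(sorted(truth.gene_module), 2):
            if truth.gene_module[a] == truth.gene_module[b]:
                assert net.has_edge(a, b)
            else:
                assert not net.has_edge(a, b)

    def test_impossible_cutoff_gives_empty_network(self, toy_matrix):
        net = build_network(toy_matrix, rho_cutoff=1.01)
        assert net.number_of_edges() == 0

    def test_constant_gene_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            np.vstack([rng.gamma(2, 5, size=(2, 8)), np.full(8, 3.0)]),
            index=["a", "b", "flat"],
            columns=[f"s{i}" for i in range(8)],
        )
        m = ExpressionMatrix(values, pd.Series(
            {"a": "coding", "b": "coding", "flat": "coding"}))
        with caplog.at_level("WARNING"):
            net = build_network(m)
        assert "flat" not in net
        assert any("constant" in r.message for r in caplog.records)

    def test_too_few_samples_rejected(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1, 2, 3], [4, 5, 6]], index=["a", "b"],
                         columns=["s0", "s1", "s2"]),
            pd.Series({"a": "coding", "b": "coding"}),
        )
        with pytest.raises(EdgeTestError):
            build_network(m)


class TestClassifyEdges:
    def test_lnc_only_network(self):
        g = nx.Graph()
        g.add_edge("l1", "l2", category="lnc-lnc")
        out = classify_edges(g)
        assert out["fractions"]["lnc-lnc"] == 1.0

    def test_empty_network_flagged_undefined(self):
        out = classify_edges(nx.Graph())
        assert out["total"] == 0 and out["undefined"]

    def test_fraction_arithmetic(self):
        out = edge_category_fractions(
            {"coding-coding": 3, "coding-lnc": 1, "lnc-lnc": 0}
        )
        assert out["total"] == 4
        assert out["display"]["coding-coding"] == 75.0


class TestGraphStatistics:
    def test_triangle_and_path(self):
        tri = nx.complete_graph(3)
        c, per = clustering_coefficient(tri)
        assert c == 1.0 and all(v == 1.0 for v in per.values())
        path = nx.path_graph(3)
        c, _ = clustering_coefficient(path)
        assert c == 0.0
        assert transitivity(path) == 0.0

    def test_star_has_no_triangles(self):
        star = nx.star_graph(5)
        assert transitivity(star) == 0.0

    @pytest.mark.parametrize("n", [3, 7, 20])
    def test_complete_graph_transitivity_one(self, n):
        assert transitivity(nx.complete_graph(n)) == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.6)),
                                seed=int(rng.integers(2**31)))
        c, per_node, t = brute_force_c_t(g)
        c_impl, per_impl = clustering_coefficient(g)
        assert c_impl == pytest.approx(c, abs=1e-12)
        assert per_impl == pytest.approx(per_node, abs=1e-12)
        assert transitivity(g) == pytest.approx(t, abs=1e-12)
        # independent library cross-check
        assert c_impl == pytest.approx(nx.average_clustering(g, count_zeros=True))
        assert transitivity(g) == pytest.approx(nx.transitivity(g))


class TestSweepAndEgo:
    def test_sweep_monotone_and_consistent(self, small_dataset):
        matrix, _ = small_dataset
        table = network_sweep(matrix, [0.3, 0.5, 0.7])
        assert list(table.cutoff) == [0.3, 0.5, 0.7]
        assert table.edges.is_monotonic_decreasing
        assert table.nodes.is_monotonic_decreasing
        single = network_sweep(matrix, [0.5]).iloc[0]
        net = build_network(matrix, 0.5)
        s = network_stats(net)
        assert single.edges == s["n_edges"]
        assert single.transitivity == pytest.approx(s["transitivity"])

    def test_noise_free_clustering_is_one(self, noise_free_dataset):
        matrix, _ = noise_free_dataset
        table = network_sweep(matrix, [0.3, 0.9])
        assert (table.clustering_coefficient == 1.0).all()

    def test_empty_cutoffs_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            network_sweep(toy_matrix, [])

    def test_ego_isolated_and_star_and_filter(self):
        g = nx.Graph()
        g.add_node("solo", biotype="lncRNA")
        sub = ego_subnetwork(g, "solo")
        assert sub.number_of_nodes() == 1 and sub.number_of_edges() == 0

        star = nx.star_graph(4)
        hub = 0
        nx.set_node_attributes(star, "coding", "biotype")
        star.nodes[1]["biotype"] = "lncRNA"
        assert ego_subnetwork(star, hub).number_of_nodes() == 5
        coding_only = ego_subnetwork(star, hub, "coding")
        assert 1 not in coding_only and coding_only.number_of_nodes() == 4

    def test_ego_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            ego_subnetwork(nx.Graph(), "ghost")

    def test_edge_list_round_trip(self, small_dataset, tmp_path):
        matrix, _ = small_dataset
        net = build_network(matrix, 0.5)
        write_edge_list(net, tmp_path / "edges.tsv")
        back = read_edge_list(tmp_path / "edges.tsv", biotype=matrix.biotype)
        assert set(back.edges) == set(net.edges)
        for a, b in net.edges:
            assert back.edges[a, b]["rs"] == pytest.approx(net.edges[a, b]["rs"])
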