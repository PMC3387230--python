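import networkx as nx
import numpy as np
import pytest

import radrank as rr
from radrank.netscore import UNREACHABLE, _directed_score_matrix

from conftest import make_network


def path_oracle(net):
    """Independent all-pairs oracle via networkx path enumeration.

    N from BFS hop counts + 1; R as the maximum reference total over all
    enumerated shortest paths.
    """
    nodes = sorted(net.nodes)
    n = len(nodes)
    N = np.full((n, n), np.inf)
    R = np.full((n, n), np.inf)
    hops = dict(nx.all_pairs_shortest_path_length(net))
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if u == v:
                N[i, j], R[i, j] = 1.0, 0.0
            elif v in hops.get(u, {}):
                N[i, j] = hops[u][v] + 1
                best = -np.inf
                for path in nx.all_shortest_paths(net, u, v):
                    total = sum(
                        net[a][b]["ref_count"] for a, b in zip(path, path[1:])
                    )
                    best = max(best, total)
                R[i, j] = best
    return nodes, N, R


def random_digraph(rng, n_nodes, edge_prob, max_ref=6):
    net = rr.new_network()
    net.add_nodes_from(f"N{i}" for i in range(n_nodes))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_prob:
                rr.add_interaction(
                    net, f"N{i}", f"N{j}", ref_count=int(rng.integers(1, max_ref + 1))
                )
    return net


class TestFloydWarshallUnit:
    def test_single_edge(self):
        net = make_network([("A", "B", 5)])
        pm = rr.floyd_warshall_unit(net)
        a, b = pm.index("A"), pm.index("B")
        assert pm.n_counts[a, b] == 2 and pm.ref_totals[a, b] == 5
        assert pm.n_counts[b, a] == UNREACHABLE
        assert pm.n_counts[a, a] == 1 and pm.ref_totals[a, a] == 0

    def test_chain_composition(self, chain_net):
        pm = rr.floyd_warshall_unit(chain_net)
        a, c = pm.index("A"), pm.index("C")
        assert pm.n_counts[a, c] == 3 and pm.ref_totals[a, c] == 2

    def test_tie_broken_toward_max_reference_total(self):
        # two 2-hop routes A->C: via B (refs 1+1) and via D (refs 5+5)
        net = make_network(
            [("A", "B", 1), ("B", "C", 1), ("A", "D", 5), ("D", "C", 5)]
        )
        pm = rr.floyd_warshall_unit(net)
        assert pm.ref_totals[pm.index("A"), pm.index("C")] == 10

    def test_shorter_path_beats_heavier_long_path(self):
        net = make_network(
            [("A", "C", 1), ("A", "B", 50), ("B", "C", 50)]
        )
        pm = rr.floyd_warshall_unit(net)
        a, c = pm.index("A"), pm.index("C")
        assert pm.n_counts[a, c] == 2 and pm.ref_totals[a, c] == 1

    def test_matches_enumeration_oracle_on_random_digraphs(self, rng):
        for trial in range(40):
            n = int(rng.integers(2, 11))
            net = random_digraph(rng, n, float(rng.uniform(0.1, 0.6)))
            pm = rr.floyd_warshall_unit(net)
            nodes, N, R = path_oracle(net)
            assert pm.nodes == nodes
            np.testing.assert_array_equal(pm.n_counts, N)
            np.testing.assert_array_equal(pm.ref_totals, R)

    def test_adding_edge_never_increases_n(self, rng):
        for _ in range(15):
            net = random_digraph(rng, 8, 0.2)
            before = rr.floyd_warshall_unit(net).n_counts
            non_edges = [
                (u, v)
                for u in net.nodes
                for v in net.nodes
                if u != v and not net.has_edge(u, v)
            ]
            if not non_edges:
                continue
            u, v = non_edges[int(rng.integers(len(non_edges)))]
            rr.add_interaction(net, u, v, ref_count=1)
            after = rr.floyd_warshall_unit(net).n_counts
            assert np.all(after <= before)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rr.floyd_warshall_unit(rr.new_network())


class TestPairScores:
    @pytest.mark.parametrize(
        "n,r,expected",
        [(2, 4, 2.25), (2, 1, 1.25), (3, 2, 2**0.5 + 1 / 9)],
    )
    def test_default_closed_forms(self, n, r, expected):
        assert rr.pair_score_directed(n, r) == pytest.approx(expected)

    def test_unreachable_scores_zero(self):
        assert rr.pair_score_directed(UNREACHABLE, UNREACHABLE) == 0.0

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            rr.pair_score_directed(1, 1)
        with pytest.raises(ValueError):
            rr.pair_score_directed(2, 0)

    def test_custom_params(self):
        params = rr.ScoreParams(alpha=1.0, beta=1.0, w_r=2.0, w_n=3.0)
        # 2*r + 3/n
        assert rr.pair_score_directed(4, 5, params) == pytest.approx(10 + 0.75)

    def test_intermediate_only_counting(self):
        params = rr.ScoreParams(count_endpoints=False)
        # direct edge: no intermediate nodes, node term collapses to w_n
        assert rr.pair_score_directed(2, 1, params) == pytest.approx(2.0)
        # one intermediate node: n_eff = 1
        assert rr.pair_score_directed(3, 2, params) == pytest.approx(2**0.5 + 1)

    def test_final_takes_directional_max(self):
        net = make_network([("A", "B", 1)])
        assert rr.pair_score_final(net, "A", "B") == pytest.approx(1.25)
        assert rr.pair_score_final(net, "B", "A") == pytest.approx(1.25)

    def test_symmetric_network_symmetric_scores(self):
        net = make_network([("A", "B", 3), ("B", "A", 3), ("B", "C", 2), ("C", "B", 2)])
        assert rr.pair_score_final(net, "A", "C") == pytest.approx(
            rr.pair_score_final(net, "C", "A")
        )

    def test_isolated_pair_scores_zero(self):
        net = rr.new_network()
        net.add_nodes_from(["A", "B"])
        assert rr.pair_score_final(net, "A", "B") == 0.0

    def test_absent_node_rejected(self):
        net = make_network([("A", "B", 1)])
        with pytest.raises(KeyError):
            rr.pair_score_final(net, "A", "Z")


class TestProteinScore:
    def test_single_edge_both_ends(self):
        net = make_network([("A", "B", 1)])
        assert rr.protein_score(net, "A") == pytest.approx(1.25)
        assert rr.protein_score(net, "B") == pytest.approx(1.25)

    def test_isolated_node_zero(self):
        net = make_network([("A", "B", 1)])
        net.add_node("Z")
        assert rr.protein_score(net, "Z") == 0.0

    def test_toy_network_matches_brute_force(self, rng):
        net = random_digraph(rng, 5, 0.5)
        nodes, N, R = path_oracle(net)
        params = rr.ScoreParams()
        for i, a in enumerate(nodes):
            expected = 0.0
            for j, b in enumerate(nodes):
                if i == j:
                    continue
                s_ab = (
                    R[i, j] ** 0.5 + N[i, j] ** -2.0 if np.isfinite(N[i, j]) else 0.0
                )
                s_ba = (
                    R[j, i] ** 0.5 + N[j, i] ** -2.0 if np.isfinite(N[j, i]) else 0.0
                )
                expected += max(s_ab, s_ba)
            assert rr.protein_score(net, a, params) == pytest.approx(expected)

    def test_monotone_in_edge_ref_count(self, rng):
        # raising any edge's reference count never lowers any protein score
        for _ in range(10):
            net = random_digraph(rng, 7, 0.3)
            if net.number_of_edges() == 0:
                continue
            pm = rr.floyd_warshall_unit(net)
            before_R = pm.ref_totals.copy()
            before = {v: rr.protein_score(net, v) for v in net.nodes}
            edges = list(net.edges)
            u, v = edges[int(rng.integers(len(edges)))]
            net[u][v]["ref_count"] += int(rng.integers(1, 5))
            after_R = rr.floyd_warshall_unit(net).ref_totals
            finite = np.isfinite(before_R)
            assert np.all(after_R[finite] >= before_R[finite])
            for node, s in before.items():
                assert rr.protein_score(net, node) >= s - 1e-12


class TestRankNetwork:
    def test_edgeless_network_all_zero_alphabetical(self):
        net = rr.new_network()
        net.add_nodes_from(["C", "A", "B"])
        table = rr.rank_network(net)
        assert list(table["gene"]) == ["A", "B", "C"]
        assert (table["score"] == 0).all()
        assert (table["n_edges"] == 0).all()

    def test_out_star_hub_outranks_leaves(self):
        # directed out-star: leaves are mutually unreachable, so the hub sums
        # k direct-edge scores while each leaf holds a single one
        net = make_network([("HUB", f"L{i}", 1) for i in range(4)])
        table = rr.rank_network(net).set_index("gene")
        hub = table.loc["HUB", "score"]
        assert hub == pytest.approx(4 * 1.25)
        for i in range(4):
            leaf = table.loc[f"L{i}", "score"]
            assert leaf == pytest.approx(1.25)
            assert hub > leaf
        assert table.loc["HUB", "n_edges"] == 4

    def test_bidirectional_star_leaf_paths_accumulate_references(self):
        # with return edges, leaf-leaf 2-hop paths carry r=2 and n=3, so each
        # leaf scores 1.25 + 3*(sqrt(2) + 1/9) — closed form from the
        # scoring definition, exceeding the hub's 4*1.25
        net = make_network(
            [("HUB", f"L{i}", 1) for i in range(4)]
            + [(f"L{i}", "HUB", 1) for i in range(4)]
        )
        table = rr.rank_network(net).set_index("gene")
        assert table.loc["HUB", "score"] == pytest.approx(5.0)
        leaf_expected = 1.25 + 3 * (np.sqrt(2) + 1 / 9)
        for i in range(4):
            assert table.loc[f"L{i}", "score"] == pytest.approx(leaf_expected)

    def test_insertion_order_invariance(self, rng):
        edges = [("B", "A", 2), ("C", "B", 3), ("A", "C", 1)]
        t1 = rr.rank_network(make_network(edges))
        t2 = rr.rank_network(make_network(edges[::-1]))
        assert t1.equals(t2)

    def test_annotations_joined(self):
        import pandas as pd

        net = make_network([("A", "B", 1)])
        ann = pd.DataFrame({"p_value": [0.01]}, index=["A"])
        table = rr.rank_network(net, annotations=ann).set_index("gene")
        assert table.loc["A", "p_value"] == 0.01
        assert np.isnan(table.loc["B", "p_value"])

    def test_matrix_scores_match_scalar_api(self, rng):
        net = random_digraph(rng, 8, 0.3)
        table = rr.rank_network(net).set_index("gene")
        for v in net.nodes:
            assert table.loc[v, "score"] == pytest.approx(rr.protein_score(net, v))

    def test_symmetric_unit_network_regression(self):
        # all ref counts 1 on a symmetric 4-cycle: ranking is purely topological
        cycle = ["A", "B", "C", "D"]
        edges = []
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            edges += [(a, b, 1), (b, a, 1)]
        table = rr.rank_network(make_network(edges))
        assert len(set(np.round(table["score"], 12))) == 1  # all symmetric


def test_score_params_validation():
    with pytest.raises(ValueError):
        rr.ScoreParams(alpha=0)
    with pytest.raises(ValueError):
        rr.ScoreParams(beta=-1)
    with pytest.warns(UserWarning, match="dominate"):
        rr.ScoreParams(alpha=0.9, beta=0.5)


def test_directed_score_matrix_consistent_with_scalar(rng):
    net = random_digraph(rng, 6, 0.4)
    pm = rr.floyd_warshall_unit(net)
    params = rr.ScoreParams()
    M = _directed_score_matrix(pm, params)
    for i in range(len(pm.nodes)):
        for j in range(len(pm.nodes)):
            if i == j:
                continue
            assert M[i, j] == pytest.approx(
                rr.pair_score_directed(pm.n_counts[i, j], pm.ref_totals[i, j], params)
            )
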