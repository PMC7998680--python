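import math

import networkx as nx
import numpy as np
import pytest

from otunet import (
    ModulePartition,
    NetworkRecord,
    RoleThresholds,
    classify_roles,
    detect_modules,
    diff_merge,
    network_summary,
    within_module_z,
    z_pi,
)
from otunet.ensemble import EnsembleEdge
from otunet.tables_io import ValidationError
from otunet.topology import NodeTopology


def _edge(a, b, sign="copresence"):
    return EnsembleEdge((a, b), sign, frozenset({"pearson", "spearman", "kl_sym"}),
                        {"pearson": 0.001}, 0.001, 0.01)


def _net(edges, attrs=None):
    nodes = {t for e in edges for t in e.pair}
    return NetworkRecord(nodes, edges, attrs or {})


class TestDetectModules:
    def test_two_disjoint_cliques_two_modules(self):
        g = nx.Graph()
        for off in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(f"n{off + i}", f"n{off + j}")
        part = detect_modules(g)
        assert part.n_modules == 2
        first = {n for n, m in part.assignment.items() if m == part.assignment["n0"]}
        assert first == {f"n{i}" for i in range(5)}

    def test_single_edge_one_module(self):
        part = detect_modules(_net([_edge("a", "b")]))
        assert part.n_modules == 1
        assert part.assignment == {"a": 0, "b": 0}

    def test_isolated_nodes_become_singletons(self):
        net = NetworkRecord({"a", "b", "c"}, [_edge("a", "b")], {})
        part = detect_modules(net)
        assert part.n_modules == 2
        assert part.assignment["c"] != part.assignment["a"]

    def test_empty_network(self):
        part = detect_modules(NetworkRecord(set(), [], {}))
        assert part.n_modules == 0 and part.assignment == {}

    def test_module_ids_contiguous_from_zero(self):
        g = nx.gnp_random_graph(30, 0.1, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(30)})
        part = detect_modules(g)
        assert set(part.assignment.values()) == set(range(part.n_modules))

    def test_deterministic(self):
        g = nx.gnp_random_graph(40, 0.08, seed=9)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(40)})
        assert detect_modules(g).assignment == detect_modules(g).assignment


class TestZPi:
    def test_within_module_z_hand_values(self):
        z = within_module_z([1, 2, 3])
        sd = math.sqrt(2.0 / 3.0)  # population sd of {1,2,3}
        np.testing.assert_allclose(z, [(1 - 2) / sd, 0.0, (3 - 2) / sd])
        assert z[2] == pytest.approx(1.2247, abs=1e-4)

    def test_degenerate_module_gives_zero(self):
        np.testing.assert_array_equal(within_module_z([2, 2, 2]), [0.0, 0.0, 0.0])

    def test_all_links_internal_gives_pi_zero(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(4)})
        part = ModulePartition({n: 0 for n in g.nodes}, 1, 0.0)
        for t in z_pi(g, part):
            assert t.pi == 0.0

    def test_two_two_split_gives_pi_half(self):
        g = nx.Graph()
        g.add_edges_from([("h", "a1"), ("h", "a2"), ("h", "b1"), ("h", "b2")])
        assignment = {"h": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        part = ModulePartition(assignment, 2, 0.0)
        h = next(t for t in z_pi(g, part) if t.node == "h")
        assert h.pi == pytest.approx(0.5)
        assert h.degree == 4 and h.within_module_degree == 2

    def test_isolated_node_pi_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b")
        part = ModulePartition({"a": 0, "b": 0, "c": 1}, 2, 0.0)
        c = next(t for t in z_pi(g, part) if t.node == "c")
        assert c.pi == 0.0 and c.z == 0.0

    def test_z_zero_mean_within_modules_and_pi_range(self):
        g = nx.gnp_random_graph(50, 0.08, seed=12)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(50)})
        part = detect_modules(g)
        tops = z_pi(g, part)
        for t in tops:
            assert 0.0 <= t.pi < 1.0
            assert 0 <= t.within_module_degree <= t.degree
        by_mod = {}
        for t in tops:
            by_mod.setdefault(t.module, []).append(t.z)
        for zs in by_mod.values():
            assert abs(np.mean(zs)) < 1e-9

    def test_node_missing_from_partition_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.raises(ValidationError):
            z_pi(g, ModulePartition({"a": 0}, 1, 0.0))


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "z,pi,expected",
        [
            (0.0, 0.0, "peripheral"),
            (2.5, 0.62, "peripheral"),  # boundaries inclusive below
            (2.5000001, 0.62, "module_hub"),
            (2.5, 0.6200001, "connector"),
            (1.0, 0.7, "connector"),
            (3.0, 0.1, "module_hub"),
            (3.0, 0.7, "network_hub"),
        ],
    )
    def test_quadrants(self, z, pi, expected):
        t = NodeTopology("n", 5, 3, 0, z, pi)
        assert classify_roles([t], RoleThresholds())[0].role == expected

    def test_every_node_gets_exactly_one_role(self):
        rng = np.random.default_rng(3)
        tops = [
            NodeTopology(f"n{i}", 4, 2, 0, rng.normal(2.5, 1), rng.uniform(0, 1))
            for i in range(100)
        ]
        roles = [t.role for t in classify_roles(tops)]
        assert all(r in {"peripheral", "connector", "module_hub", "network_hub"} for r in roles)


class TestDiffMerge:
    def test_set_difference_semantics(self):
        e1, e2, e3 = _edge("a", "b"), _edge("b", "c"), _edge("c", "d")
        net_a = _net([e1, e2], {"treatment": "synbiotic"})
        net_b = _net([e2, e3], {"treatment": "placebo"})
        merged = diff_merge([net_a, net_b])
        by_pair = {e.pair: e for e in merged.edges}
        assert set(by_pair) == {("a", "b"), ("c", "d")}
        assert by_pair[("a", "b")].sources == frozenset({"synbiotic"})
        assert by_pair[("c", "d")].sources == frozenset({"placebo"})
        assert merged.nodes == {"a", "b", "c", "d"}

    def test_identical_networks_empty_difference(self):
        edges = [_edge("a", "b"), _edge("b", "c")]
        net = _net(edges, {"treatment": "synbiotic"})
        net2 = _net(list(edges), {"treatment": "placebo"})
        assert diff_merge([net, net2]).edges == []

    def test_opposite_signs_both_retained(self):
        net_a = _net([_edge("a", "b", "copresence")], {"treatment": "synbiotic"})
        net_b = _net([_edge("a", "b", "exclusion")], {"treatment": "placebo"})
        merged = diff_merge([net_a, net_b])
        assert {(e.pair, e.sign) for e in merged.edges} == {
            (("a", "b"), "copresence"),
            (("a", "b"), "exclusion"),
        }

    def test_symmetric_in_argument_order(self):
        net_a = _net([_edge("a", "b")], {"treatment": "synbiotic"})
        net_b = _net([_edge("b", "c")], {"treatment": "placebo"})
        ab = {(e.pair, e.sign) for e in diff_merge([net_a, net_b]).edges}
        ba = {(e.pair, e.sign) for e in diff_merge([net_b, net_a]).edges}
        assert ab == ba

    def test_needs_two_networks(self):
        with pytest.raises(ValidationError):
            diff_merge([_net([_edge("a", "b")])])


class TestNetworkSummary:
    def test_empty_network_all_zero(self):
        net = NetworkRecord(set(), [], {})
        part = detect_modules(net)
        s = network_summary(net, part, [])
        assert s["n_nodes"] == s["n_edges"] == s["n_modules"] == 0
        assert all(v == 0 for v in s["role_counts"].values())

    def test_role_counts_match_table(self):
        net = _net([_edge("a", "b"), _edge("b", "c"), _edge("c", "a")])
        part = detect_modules(net)
        tops = classify_roles(z_pi(net, part))
        s = network_summary(net, part, tops)
        assert sum(s["role_counts"].values()) == len(s["role_table"]) == 3
        for role, count in s["role_counts"].items():
            assert (s["role_table"]["role"] == role).sum() == count
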