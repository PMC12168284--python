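"""Association-network inference, consensus construction, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

import plaquestab as ps
from plaquestab.networks import AssociationNetwork, write_edgelist_tsv, write_graphml


def _net(edges, nodes=None):
    rows = [
        {"source": min(a, b), "target": max(a, b), "sign": s, "weight": w}
        for a, b, s, w in edges
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "sign", "weight"])
    nodes = nodes or sorted({e[0] for e in edges} | {e[1] for e in edges})
    return AssociationNetwork(nodes=list(nodes), edges=df)


def brute_force_modularity(edges, assignment):
    """Independent oracle: Q = Σ_c (e_cc − a_c²) over unweighted edges."""
    m = len(edges)
    clusters = set(assignment.values())
    q = 0.0
    for c in clusters:
        members = {n for n, cc in assignment.items() if cc == c}
        e_cc = sum(1 for a, b in edges if a in members and b in members) / m
        degree_sum = sum(
            sum(1 for e in edges if n in e) for n in members
        )
        a_c = degree_sum / (2 * m)
        q += e_cc - a_c**2
    return q


class TestMbInference:
    def test_correlated_pair_yields_positive_edge(self):
        rng = np.random.default_rng(0)
        n = 120
        shared = rng.normal(size=n)
        data = pd.DataFrame(
            {
                "sp_a": shared + rng.normal(0, 0.1, n),
                "sp_b": shared + rng.normal(0, 0.1, n),
                "sp_c": rng.normal(size=n),
                "sp_d": rng.normal(size=n),
                "sp_e": rng.normal(size=n),
            }
        )
        net = ps.infer_network_mb(data, seed=1)
        edges = {(r["source"], r["target"]): r["sign"] for _, r in net.edges.iterrows()}
        assert edges.get(("sp_a", "sp_b")) == "+"

    def test_independent_columns_give_sparse_graph(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            rng.normal(size=(300, 15)), columns=[f"sp_{i:02d}" for i in range(15)]
        )
        net = ps.infer_network_mb(data, seed=2)
        density = len(net.edges) / (15 * 14 / 2)
        assert density <= 0.05

    def test_too_few_samples_rejected(self):
        data = pd.DataFrame(np.random.default_rng(2).normal(size=(10, 5)))
        with pytest.raises(ValueError, match="at least"):
            ps.infer_network_mb(data)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        data["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            net = ps.infer_network_mb(data, seed=0, stars_reps=5)
        assert "const" not in net.nodes

    def test_sign_flip_in_simulation_flips_edge_sign(self):
        data_pos, _, _ = ps.simulate_ggm(12, 3, 400, seed=9)
        data_neg, _, _ = ps.simulate_ggm(12, 3, 400, seed=9, flip_edge=(0, 1))
        net_pos = ps.infer_network_mb(data_pos, seed=4)
        net_neg = ps.infer_network_mb(data_neg, seed=4)

        def sign_of(net, a, b):
            sub = net.edges[(net.edges["source"] == a) & (net.edges["target"] == b)]
            return sub["sign"].iloc[0] if len(sub) else None

        assert sign_of(net_pos, "species_001", "species_002") == "+"
        assert sign_of(net_neg, "species_001", "species_002") == "-"


class TestCan:
    def test_identical_networks_intersection_is_identity(self):
        net = _net([("a", "b", "+", 0.5), ("b", "c", "-", -0.2)])
        can = ps.build_can([net, net, net], 1.0)
        assert can.edge_set() == net.edge_set()

    def test_set_size_thresholds(self):
        shared = [("a", "b", "+", 0.5)]
        extra = [("b", "c", "+", 0.3)]
        nets = [_net(shared + extra), _net(shared + extra), _net(shared)]
        full = ps.build_can(nets, 1.0)
        majority = ps.build_can(nets, 0.6)  # ceil(0.6 × 3) = 2
        assert ("b", "c") not in full.edge_set()
        assert ("b", "c") in majority.edge_set()
        assert ("a", "b") in full.edge_set()

    def test_intersection_subset_of_every_input(self):
        rng = np.random.default_rng(5)
        nets = []
        nodes = list("abcdef")
        for _ in range(3):
            edges = [
                (a, b, "+", 1.0)
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.5
            ]
            nets.append(_net(edges, nodes))
        can = ps.build_can(nets, 1.0)
        for net in nets:
            assert can.edge_set() <= net.edge_set()

    def test_raising_set_size_never_adds_edges(self):
        rng = np.random.default_rng(6)
        nodes = list("abcde")
        nets = [
            _net(
                [(a, b, "+", 1.0) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.6],
                nodes,
            )
            for _ in range(4)
        ]
        previous = None
        for frac in (0.25, 0.5, 0.75, 1.0):
            edges = ps.build_can(nets, frac).edge_set()
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_sign_majority_and_tie_drop(self):
        e_pos = [("a", "b", "+", 0.5)]
        e_neg = [("a", "b", "-", -0.5)]
        tie = ps.build_can([_net(e_pos), _net(e_neg)], 0.5)
        assert tie.edge_set() == set()
        majority = ps.build_can([_net(e_pos), _net(e_pos), _net(e_neg)], 0.5)
        assert majority.edges["sign"].iloc[0] == "+"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ps.build_can([], 1.0)


class TestModularity:
    def test_two_disjoint_triangles_q_half(self):
        net = _net(
            [("a", "b", "+", 1), ("b", "c", "+", 1), ("a", "c", "+", 1),
             ("x", "y", "+", 1), ("y", "z", "+", 1), ("x", "z", "+", 1)]
        )
        part = ps.greedy_modularity(net)
        assert part.modularity == pytest.approx(0.5, abs=1e-12)
        assert len(part.sizes) == 2
        assert part.assignment["a"] == part.assignment["b"] == part.assignment["c"]

    def test_complete_graph_single_cluster_q_zero(self):
        nodes = list("abcd")
        net = _net([(a, b, "+", 1) for a, b in itertools.combinations(nodes, 2)])
        part = ps.greedy_modularity(net)
        assert part.modularity == pytest.approx(0.0, abs=1e-12)
        assert len(part.sizes) == 1

    def test_q_matches_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            nodes = [f"n{i}" for i in range(rng.integers(5, 12))]
            edges = [
                (a, b)
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.4
            ]
            if not edges:
                continue
            net = _net([(a, b, "+", 1.0) for a, b in edges], nodes)
            part = ps.greedy_modularity(net)
            oracle = brute_force_modularity(edges, {
                n: part.assignment[n]
                for n in set().union(*[set(e) for e in edges])
            })
            assert part.modularity == pytest.approx(oracle, abs=1e-12)

    def test_edgeless_graph_singletons_with_warning(self):
        net = AssociationNetwork(
            nodes=["a", "b"],
            edges=pd.DataFrame(columns=["source", "target", "sign", "weight"]),
        )
        with pytest.warns(UserWarning, match="edgeless"):
            part = ps.greedy_modularity(net)
        assert part.modularity == 0.0
        assert part.sizes == {1: 1, 2: 1}

    def test_deterministic_partitions(self):
        data, _, _ = ps.simulate_ggm(15, 3, 200, seed=11)
        net = ps.infer_network_mb(data, seed=5)
        p1 = ps.greedy_modularity(net)
        p2 = ps.greedy_modularity(net)
        assert p1.assignment == p2.assignment


class TestClusterReporting:
    def test_min_size_rule(self):
        edges = [(f"a{i}", f"a{j}", "+", 1.0) for i, j in itertools.combinations(range(10), 2)]
        edges += [("x", "y", "+", 1.0), ("y", "z", "+", 1.0), ("x", "z", "+", 1.0)]
        part = ps.greedy_modularity(_net(edges))
        view = ps.filter_clusters(part, min_size=10)
        big = view[view["node"].str.startswith("a")]
        small = view[view["node"].isin(["x", "y", "z"])]
        assert big["in_reported_set"].all()
        assert not small["in_reported_set"].any()

    def test_nine_member_cluster_excluded_ten_included(self):
        e9 = [(f"a{i}", f"a{j}", "+", 1.0) for i, j in itertools.combinations(range(9), 2)]
        e10 = [(f"b{i}", f"b{j}", "+", 1.0) for i, j in itertools.combinations(range(10), 2)]
        part = ps.greedy_modularity(_net(e9 + e10))
        view = ps.filter_clusters(part, min_size=10).set_index("node")
        assert not view.loc["a0", "in_reported_set"]
        assert view.loc["b0", "in_reported_set"]

    def test_exclusion_does_not_change_q(self):
        edges = [("a", "b", "+", 1.0), ("c", "d", "+", 1.0)]
        part = ps.greedy_modularity(_net(edges))
        q_before = part.modularity
        ps.filter_clusters(part, min_size=10)
        assert part.modularity == q_before


class TestOverlay:
    def test_overlay_labels_and_unique_nodes(self):
        global_net = _net([("a", "b", "+", 1.0), ("c", "d", "+", 1.0)])
        global_part = ps.greedy_modularity(global_net)
        group_can = _net([("a", "b", "+", 1.0), ("e", "f", "+", 1.0)])
        overlay = ps.cluster_overlay(global_part, group_can)
        assert overlay["a"] == global_part.assignment["a"]
        assert overlay["e"] == "unique"

    def test_overlay_onto_itself_is_identity(self):
        net = _net([("a", "b", "+", 1.0), ("b", "c", "+", 1.0)])
        part = ps.greedy_modularity(net)
        overlay = ps.cluster_overlay(part, net)
        assert overlay == part.assignment


def test_exports_write_readable_files(tmp_path):
    net = _net([("a", "b", "+", 0.4)])
    write_edgelist_tsv(net, tmp_path / "edges.tsv")
    write_graphml(net, tmp_path / "net.graphml")
    df = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert list(df.columns) == ["source", "target", "sign", "weight"]
    assert (tmp_path / "net.graphml").read_text().startswith("<?xml")
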