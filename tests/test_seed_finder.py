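"""Seed-set detection: SCCs, condensation, seed groups, thresholds."""

from fractions import Fraction

import networkx as nx
import pytest

from netcooperate import (
    brute_force_seed_oracle,
    condensation,
    find_seed_set,
    is_seed,
    random_network,
    seed_table,
    strongly_connected_components,
)

from conftest import net_from_edges


def transitive_closure_scc(net):
    """Independent SCC oracle: mutual reachability via Floyd–Warshall-style
    boolean closure."""
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = [[i == j for j in range(n)] for i in range(n)]
    for u, v in net.edges:
        reach[idx[u]][idx[v]] = True
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                row_i, row_k = reach[i], reach[k]
                for j in range(n):
                    if row_k[j]:
                        row_i[j] = True
    comps = {}
    for i, node in enumerate(nodes):
        key = frozenset(
            nodes[j] for j in range(n) if reach[i][j] and reach[j][i]
        )
        comps[key] = None
    return set(comps)


def random_suite(count, n_max=12, seed0=0, p=0.25):
    return [
        random_network(3 + s % (n_max - 2), p, seed0 + s) for s in range(count)
    ]


def test_scc_single_cycle():
    net = net_from_edges("cyc", [("F", "G"), ("G", "H"), ("H", "F")])
    assert strongly_connected_components(net) == [frozenset({"F", "G", "H"})]


def test_scc_chain_is_singletons():
    net = net_from_edges("chain", [("A", "B"), ("B", "C")])
    assert strongly_connected_components(net) == [
        frozenset({"A"}),
        frozenset({"B"}),
        frozenset({"C"}),
    ]


def test_scc_matches_transitive_closure_oracle():
    for net in random_suite(50):
        ours = set(strongly_connected_components(net))
        assert ours == transitive_closure_scc(net), net.name


def test_scc_matches_networkx():
    for net in random_suite(30, seed0=500):
        g = nx.DiGraph(sorted(net.edges))
        g.add_nodes_from(sorted(net.nodes))
        theirs = {frozenset(c) for c in nx.strongly_connected_components(g)}
        assert set(strongly_connected_components(net)) == theirs, net.name


def test_condensation_path():
    net = net_from_edges("chain", [("A", "B"), ("B", "C")])
    comps, dag = condensation(net)
    assert comps == [frozenset({"A"}), frozenset({"B"}), frozenset({"C"})]
    assert dag == {(0, 1), (1, 2)}


def test_condensation_contracts_cycle():
    net = net_from_edges("cycfeed", [("F", "G"), ("G", "H"), ("H", "F"), ("F", "D")])
    comps, dag = condensation(net)
    assert len(comps) == 2
    assert len(dag) == 1


def test_condensation_acyclic_and_sources_match_indegree():
    for net in random_suite(40, seed0=100):
        comps, dag = condensation(net)
        g = nx.DiGraph(sorted(dag))
        g.add_nodes_from(range(len(comps)))
        assert nx.is_directed_acyclic_graph(g)
        # sources computed independently from raw edges
        comp_of = {n: i for i, c in enumerate(comps) for n in c}
        indeg = {i: 0 for i in range(len(comps))}
        for u, v in net.edges:
            if comp_of[u] != comp_of[v]:
                indeg[comp_of[v]] += 1
        dag_sources = {i for i in indeg if i not in {j for _, j in dag}}
        assert dag_sources == {i for i, d in indeg.items() if d == 0}


def test_blue_fixture_seed_groups(blue):
    seed_set = find_seed_set(blue)
    groups = {g.compounds for g in seed_set.groups}
    assert groups == {frozenset({"A"}), frozenset({"F", "G", "H"})}
    confidences = sorted(g.confidence for g in seed_set.groups)
    assert confidences == [Fraction(1, 3), Fraction(1, 1)]


def test_three_cycle_is_one_group():
    net = net_from_edges("tri", [("A", "B"), ("B", "C"), ("C", "A")])
    seed_set = find_seed_set(net)
    assert [g.compounds for g in seed_set.groups] == [frozenset({"A", "B", "C"})]


def test_self_loop_only_node_is_seed():
    net = net_from_edges("loop", [("X", "X"), ("X", "Y")])
    assert find_seed_set(net).seed_compounds == {"X"}


def test_isolated_nodes_are_singleton_seeds():
    net = net_from_edges("iso", [("A", "B")], extra_nodes=["Q", "R"])
    groups = {g.compounds for g in find_seed_set(net).groups}
    assert groups == {frozenset({"A"}), frozenset({"Q"}), frozenset({"R"})}


def test_seed_groups_match_exhaustive_oracle():
    for net in random_suite(60, n_max=10, seed0=200):
        predicted = frozenset(g.compounds for g in find_seed_set(net).groups)
        assert predicted == brute_force_seed_oracle(net), net.name


def test_seed_compounds_reach_all_nodes():
    for net in random_suite(30, seed0=300):
        seed_set = find_seed_set(net)
        g = nx.DiGraph(sorted(net.edges))
        g.add_nodes_from(sorted(net.nodes))
        reachable = set(seed_set.seed_compounds)
        for s in seed_set.seed_compounds:
            reachable |= nx.descendants(g, s)
        assert reachable == set(net.nodes), net.name


def test_single_representative_per_group_suffices():
    """Picking any one compound per seed group still reaches every node."""
    import random as pyrandom

    rng = pyrandom.Random(7)
    for net in random_suite(10, seed0=400):
        seed_set = find_seed_set(net)
        g = nx.DiGraph(sorted(net.edges))
        g.add_nodes_from(sorted(net.nodes))
        for _ in range(20):
            picks = [rng.choice(group.sorted_compounds) for group in seed_set.groups]
            reachable = set(picks)
            for s in picks:
                reachable |= nx.descendants(g, s)
            assert reachable == set(net.nodes), net.name


def test_group_confidences_sum_to_one_each():
    for net in random_suite(20, seed0=600):
        for group in find_seed_set(net).groups:
            assert group.confidence * len(group) == 1


def test_relabeling_maps_groups():
    net = random_network(8, 0.25, 42)
    mapping = {n: f"X_{n}" for n in net.nodes}
    relabeled = net.relabeled(mapping, name="relabeled")
    orig = {frozenset(mapping[c] for c in g.compounds) for g in find_seed_set(net).groups}
    new = {g.compounds for g in find_seed_set(relabeled).groups}
    assert orig == new


def test_feeding_a_singleton_seed_removes_it(blue):
    """Adding an edge from a non-seed node into seed A makes A producible."""
    edges = set(blue.edges) | {("B", "A")}
    fed = net_from_edges("fed", edges)
    groups = {g.compounds for g in find_seed_set(fed).groups}
    assert frozenset({"A"}) not in groups
    # A joined the cycle with B: the A/B cycle is now the source group
    assert frozenset({"A", "B"}) in groups


def test_threshold_filters_low_confidence_groups(blue):
    seed_set = find_seed_set(blue, min_confidence=0.5)
    assert {g.compounds for g in seed_set.groups} == {frozenset({"A"})}
    assert {g.compounds for g in seed_set.filtered_groups} == {frozenset({"F", "G", "H"})}
    assert seed_set.seed_compounds == {"A"}


def test_threshold_boundary_keeps_exact_confidence(blue):
    # a group of 3 has confidence exactly 1/3 and passes a 1/3 threshold
    seed_set = find_seed_set(blue, min_confidence=1 / 3)
    assert len(seed_set.groups) == 2


def test_find_seed_set_argument_errors(blue):
    with pytest.raises(ValueError):
        find_seed_set(blue, min_confidence=1.5)
    with pytest.raises(TypeError):
        find_seed_set(None)


def test_is_seed(blue):
    seed_set = find_seed_set(blue)
    assert is_seed(seed_set, "A")
    assert not is_seed(seed_set, "B")
    assert not is_seed(seed_set, "Q")  # unknown label: False, not an error


def test_seed_table_layout(blue):
    table = seed_table(find_seed_set(blue))
    assert list(table.columns) == ["group", "compound", "confidence"]
    assert list(table["compound"]) == ["A", "F", "G", "H"]
    assert list(table["group"]) == [1, 2, 2, 2]
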