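"""Co-occurrence network construction, modularity, community detection."""

import itertools
import math

import networkx as nx
import pytest

from comopat import (
    TransactionDB,
    build_network,
    chapter_partition,
    detect_communities,
    modularity,
)
from comopat.network import PartitionError


def set_partitions(items):
    """All partitions of a list into non-empty blocks (recursive, exact)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def best_partition_q(network):
    """Exhaustive-search optimum modularity (guarded to tiny graphs)."""
    nodes = list(network.graph.nodes)
    assert len(nodes) <= 8
    best = -math.inf
    for blocks in set_partitions(nodes):
        assignment = {n: i for i, block in enumerate(blocks) for n in block}
        best = max(best, modularity(network, assignment))
    return best


class TestBuildNetwork:
    def test_node_and_edge_counting(self):
        tdb = TransactionDB.from_sets([{"A", "B"}, {"A", "B"}, {"A", "C"}])
        net = build_network(tdb, ["A", "B", "C"])
        assert net.nodes == {"A": 3, "B": 2, "C": 1}
        assert net.edges == {frozenset({"A", "B"}): 2, frozenset({"A", "C"}): 1}

    def test_min_cooccurrence_prunes_edges(self):
        tdb = TransactionDB.from_sets([{"A", "B"}, {"A", "B"}, {"A", "C"}])
        net = build_network(tdb, ["A", "B", "C"], min_cooccurrence=2)
        assert set(net.edges) == {frozenset({"A", "B"})}
        assert "C" in net.nodes  # isolated node kept

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValueError):
            build_network(TransactionDB.from_sets([{"A"}]), [])

    def test_edge_weight_symmetric_and_order_invariant(self):
        sets = [{"A", "B"}, {"B", "C"}, {"A", "B", "C"}, {"C"}]
        a = build_network(TransactionDB.from_sets(sets), ["A", "B", "C"])
        b = build_network(TransactionDB.from_sets(list(reversed(sets))), ["C", "B", "A"])
        assert a.edges == b.edges and a.nodes == b.nodes

    def test_independent_diseases_edge_weight_matches_expectation(self):
        from comopat import CohortConfig, build_transactions, filter_cohort, generate_cohort
        from comopat.synthetic import catalog_for

        p = {"A": 0.10, "B": 0.08, "C": 0.12}
        cfg = CohortConfig(n_patients=20000, disease_marginals=p, rng_seed=29)
        cat = catalog_for(cfg)
        kept, _ = filter_cohort(generate_cohort(cfg), cat)
        net = build_network(build_transactions(kept, cat), list(p))
        for x, y in itertools.combinations(p, 2):
            expect = 20000 * p[x] * p[y]
            se = math.sqrt(20000 * p[x] * p[y] * (1 - p[x] * p[y]))
            assert abs(net.edges.get(frozenset({x, y}), 0) - expect) <= 3 * se


def _net_from_edges(edges):
    tdbsets = []
    for (u, v), w in edges.items():
        tdbsets.extend([{u, v}] * w)
    nodes = sorted({n for e in edges for n in e})
    return build_network(TransactionDB.from_sets(tdbsets), nodes)


class TestModularity:
    def test_two_disconnected_edges_each_own_community(self):
        net = _net_from_edges({("A", "B"): 1, ("C", "D"): 1})
        q = modularity(net, {"A": 0, "B": 0, "C": 1, "D": 1})
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_single_community_scores_zero(self):
        net = _net_from_edges({("A", "B"): 2, ("B", "C"): 1, ("A", "C"): 3})
        assert modularity(net, {"A": 0, "B": 0, "C": 0}) == pytest.approx(0.0, abs=1e-12)

    def test_missing_node_raises(self):
        net = _net_from_edges({("A", "B"): 1})
        with pytest.raises(PartitionError):
            modularity(net, {"A": 0})

    def test_agrees_with_networkx(self):
        net = _net_from_edges({("A", "B"): 3, ("B", "C"): 1, ("C", "D"): 4, ("A", "D"): 2})
        assignment = {"A": 0, "B": 0, "C": 1, "D": 1}
        communities = [{"A", "B"}, {"C", "D"}]
        q_nx = nx.community.modularity(net.graph, communities, weight="weight")
        assert modularity(net, assignment) == pytest.approx(q_nx, abs=1e-12)


class TestDetectCommunities:
    def test_two_cliques_with_weak_bridge(self):
        edges = {}
        for block in (["A", "B", "C", "D"], ["E", "F", "G", "H"]):
            for u, v in itertools.combinations(block, 2):
                edges[(u, v)] = 5
        edges[("D", "E")] = 1
        net = _net_from_edges(edges)
        part = detect_communities(net, rng_seed=0)
        assert part.n_communities == 2
        assert {frozenset(c) for c in part.communities()} == {
            frozenset("ABCD"), frozenset("EFGH")}
        assert part.modularity_q == pytest.approx(best_partition_q(net), abs=1e-9)

    def test_single_edge_graph_picks_higher_q_partition(self):
        net = _net_from_edges({("A", "B"): 1})
        part = detect_communities(net, rng_seed=0)
        q_one = modularity(net, {"A": 0, "B": 0})
        q_two = modularity(net, {"A": 0, "B": 1})
        assert part.modularity_q == pytest.approx(max(q_one, q_two), abs=1e-12)

    def test_reported_q_recomputable_from_assignment(self):
        edges = {("A", "B"): 3, ("B", "C"): 1, ("C", "D"): 4, ("A", "D"): 2, ("B", "D"): 1}
        net = _net_from_edges(edges)
        part = detect_communities(net, rng_seed=1)
        assert part.modularity_q == pytest.approx(
            modularity(net, part.assignment), abs=1e-9)

    def test_deterministic_for_fixed_seed(self):
        edges = {("A", "B"): 2, ("B", "C"): 2, ("C", "A"): 1, ("C", "D"): 3}
        net = _net_from_edges(edges)
        a = detect_communities(net, rng_seed=5)
        b = detect_communities(net, rng_seed=5)
        assert a.assignment == b.assignment and a.modularity_q == b.modularity_q


class TestChapterPartition:
    def test_groups_by_icd_chapter(self, catalog):
        tdb = TransactionDB.from_sets([
            {"Pneumonia", "Emphysema"}, {"Hypertension", "Heart failure"},
            {"Pneumonia", "Hypertension"}])
        net = build_network(tdb, ["Pneumonia", "Emphysema", "Hypertension", "Heart failure"],
                            catalog=catalog)
        part = chapter_partition(net)
        a = part.assignment
        assert a["Pneumonia"] == a["Emphysema"]  # both chapter J
        assert a["Hypertension"] == a["Heart failure"]  # both chapter I
        assert a["Pneumonia"] != a["Hypertension"]
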