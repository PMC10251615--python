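import networkx as nx
import pytest

from tigkit import dna
from tigkit.balance import (
    bi_imbalance,
    capped_min_cost_paths,
    classify,
    many_to_many_paths,
)
from tigkit.graph import ORIGINAL, BidirectedDbg, build_graph
from tigkit.fixtures import random_genome, random_pangenome


def test_simple_out_surplus():
    # CAA has 2 original out-arcs, 1 in-arc, no self-complemental arcs
    graph = build_graph(["CATTGA", "CAAACA"], 4)
    v = graph.node_lookup["CAA"]
    assert len(graph.original_out(v)) == 2
    assert len(graph.original_in(v)) == 1
    assert bi_imbalance(graph, v) == +1


def test_self_complemental_node_parity():
    # ACGT is self-complemental at k-1=4; three incident biarcs, parity 3%2=1
    graph = build_graph(["ACGTA", "ACGTC", "ACGTG"], 5)
    v = graph.node_lookup["ACGT"]
    assert graph.nodes[v].is_self_complemental
    assert len(graph.original_out(v)) == 3
    assert bi_imbalance(graph, v) == 1


def test_fig4a_binode_with_self_complemental_biarc_is_balanced():
    # [ACG, CGT] with the self-complemental biarc [(ACG,CGT)], one biarc in
    # (GACG) and one biarc out (CGTG): balanced
    graph = build_graph(["GACGTG"], 4)
    v = graph.node_lookup["ACG"]
    assert bi_imbalance(graph, v) == 0
    table = classify(graph)
    assert v not in table.demands


def test_cycle_is_balanced_path_is_not():
    cycle = build_graph(["AAGGCAAG"], 4)  # circular overlap AAG...AAG
    table = classify(cycle)
    assert table.is_bi_eulerian
    path = build_graph(["AAGGC"], 4)
    table = classify(path)
    assert len(table.sources) == 1 and len(table.sinks) == 1
    assert sum(d.units for d in table.demands.values()) == 2


def test_two_self_complemental_nodes_classified():
    # GTGTCGAGCT contains the self-complemental (k-1)-mers TCGA and AGCT;
    # both binodes land in S (self-complemental nodes exist only for odd k)
    graph = build_graph(["GTGTCGAGCT"], 5)
    self_comp = [r for r in graph.binode_reps()
                 if graph.nodes[r].is_self_complemental]
    assert {graph.nodes[r].label for r in self_comp} == {"TCGA", "AGCT"}
    table = classify(graph)
    for r in self_comp:
        assert r in table.self_complemental


def _uncapped_reference(graph, source):
    """Independent uncapped shortest paths via networkx on the doubled graph."""
    g = nx.MultiDiGraph()
    for arc in graph.arcs:
        if arc.kind == ORIGINAL:
            g.add_edge(arc.tail, arc.head, weight=arc.cost)
    if source not in g:
        return {}
    return nx.single_source_dijkstra_path_length(g, source, weight="weight")


@pytest.mark.parametrize("seed", range(25))
def test_capped_search_matches_uncapped_reference(seed):
    genome = random_genome(seed, 60)
    graph = build_graph([genome], 5)
    cap = graph.k - 1
    for source in list(graph.node_lookup.values())[:10]:
        got = dict(capped_min_cost_paths(graph, source, cap))
        want = {
            n: c
            for n, c in _uncapped_reference(graph, source).items()
            if 0 < c <= cap
        }
        assert got == want


def test_capped_search_never_exceeds_cap():
    graph = build_graph([random_genome(42, 80)], 5)
    for source in list(graph.node_lookup.values())[:20]:
        for _, cost in capped_min_cost_paths(graph, source, graph.k - 1):
            assert 1 <= cost <= graph.k - 1


def test_bieulerian_graph_has_empty_path_table():
    graph = build_graph(["AAGGCAAG"], 4)
    table = classify(graph)
    paths = many_to_many_paths(graph, table)
    assert len(paths) == 0


def test_two_components_two_entries():
    # two disconnected subgraphs, each contributing exactly one joinable pair
    graph = build_graph(["TCGATCAA", "ACATATAT"], 4)
    assert len(graph.connected_components()) == 2
    table = classify(graph)
    paths = many_to_many_paths(graph, table)
    for e in paths.entries.values():
        assert 1 <= e.cost <= graph.k - 1
    assert len(paths) == 2


def _brute_force_entries(graph, table, cap):
    """All-pairs-under-cap enumeration on the doubled graph (reference)."""
    entries = {}
    demands = table.demands
    sink_of = {d.pos: rep for rep, d in demands.items()}
    for rep, d in demands.items():
        dist = _uncapped_reference(graph, d.neg)
        for node, cost in dist.items():
            other = sink_of.get(node)
            if other is None or not 0 < cost <= cap or node == d.neg:
                continue
            if other == rep and d.self_complemental:
                continue
            key = (min(rep, other), max(rep, other))
            if key not in entries or cost < entries[key]:
                entries[key] = cost
    return entries


@pytest.mark.parametrize("seed", range(15))
def test_path_table_matches_allpairs_enumeration(seed):
    pangenome = random_pangenome(seed, 25, 3, 0.1)
    graph = build_graph(pangenome, 5)
    table = classify(graph)
    paths = many_to_many_paths(graph, table)
    want = _brute_force_entries(graph, table, graph.k - 1)
    got = {key: e.cost for key, e in paths.entries.items()}
    assert got == want


def test_path_table_independent_of_workers_and_block_size():
    pangenome = random_pangenome(5, 40, 3, 0.1)
    graph = build_graph(pangenome, 5)
    table = classify(graph)
    reference = many_to_many_paths(graph, table, threads=1)
    for threads, block in ((2, 2), (4, 1), (1, 3)):
        other = many_to_many_paths(graph, table, threads=threads,
                                   block_size=block)
        assert {k: (e.cost, e.tail, e.head) for k, e in other.entries.items()} \
            == {k: (e.cost, e.tail, e.head) for k, e in reference.entries.items()}


def test_unknown_binode_raises():
    graph = build_graph(["ACGTC"], 4)
    with pytest.raises(KeyError):
        bi_imbalance(graph, 10_000)
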