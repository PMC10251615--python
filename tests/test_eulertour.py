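from collections import Counter

import pytest

from tigkit import dna
from tigkit.balance import bi_imbalance, classify
from tigkit.eulertour import (
    bi_eulerian_circuit,
    break_circuit,
    eulerise,
    greedy_plan,
)
from tigkit.graph import (
    BREAKING,
    DUMMY,
    ORIGINAL,
    BidirectedDbg,
    Biwalk,
    GraphError,
    build_graph,
)
from tigkit.matching import EulerisationPlan, eulertigs_plan
from tigkit.fixtures import random_genome, random_pangenome


def assert_balanced(graph):
    for rep in graph.binode_reps():
        value = bi_imbalance(graph, rep, kinds="all")
        if graph.nodes[rep].is_self_complemental:
            assert value % 2 == 0
        else:
            assert value == 0


def test_bieulerian_graph_gets_one_breaking_loop():
    graph = build_graph(["AAGGCAAG"], 4)  # a single cycle
    eulerise(graph, EulerisationPlan())
    breaking = graph.iter_biarcs(BREAKING)
    assert len(breaking) == 1
    assert_balanced(graph)


def test_eulerise_rejects_unbalancing_plan():
    graph = build_graph(["ACCTC"], 4)  # simple path, needs a plan
    with pytest.raises(GraphError):
        eulerise(graph, EulerisationPlan())


def test_path_graph_balanced_by_breaking_plan():
    graph = build_graph(["ACCTC"], 4)
    plan = eulertigs_plan(classify(graph))
    assert len(plan.breaking) == 1
    eulerise(graph, plan)
    assert_balanced(graph)


@pytest.mark.parametrize("seed", range(50))
def test_eulerised_random_graphs_are_balanced(seed):
    if seed % 2:
        strings = [random_genome(seed, 30)]
    else:
        strings = random_pangenome(seed, 25, 3, 0.1)
    graph = build_graph(strings, 5)
    plan = greedy_plan(graph)
    eulerise(graph, plan)
    assert_balanced(graph)


def test_greedy_join_saves_characters_on_unique_path():
    # one source/sink pair with a connecting path of cost c <= k-1: the
    # greedy plan joins them, saving (k-1) - c over breaking
    graph = build_graph(["GCATGCATG"], 5)
    plan = greedy_plan(graph)
    assert len(plan.joining) == 1
    cost = plan.joining[0][2]
    breaking_only = eulertigs_plan(classify(build_graph(["GCATGCATG"], 5)))
    assert plan.total_cost(5) == breaking_only.total_cost(5) - ((5 - 1) - cost)


def test_greedy_without_reachable_sinks_equals_eulertigs():
    graph = build_graph(["CCTTAA", "GGGGCT"], 4)
    plan = greedy_plan(graph)
    assert not plan.joining
    reference = eulertigs_plan(classify(build_graph(["CCTTAA", "GGGGCT"], 4)))
    assert plan.total_cost(4) == reference.total_cost(4)


def test_single_cycle_circuit_uses_each_biarc_once():
    graph = build_graph(["AAGGCAAG"], 4)
    eulerise(graph, EulerisationPlan())
    circuit = bi_eulerian_circuit(graph)
    seen = Counter()
    for aid in circuit:
        rep = min(aid, graph.arcs[aid].twin)
        seen[rep] += 1
    assert set(seen) == set(graph.iter_biarcs())
    assert all(c == 1 for c in seen.values())


def test_self_complemental_biarc_covered_once():
    # the palindromic 4-mer ACGT sits between two ordinary biarcs; the
    # circuit must traverse the self-complemental biarc exactly once
    graph = build_graph(["GACGTG"], 4)
    plan = greedy_plan(graph)
    eulerise(graph, plan)
    circuit = bi_eulerian_circuit(graph)
    self_comp = [a for a in circuit if graph.arcs[a].is_self_complemental
                 and graph.arcs[a].kind == ORIGINAL]
    assert len(self_comp) == 1


@pytest.mark.parametrize("seed", range(40))
def test_circuits_cover_every_biarc_exactly_once(seed):
    strings = random_pangenome(seed, 20, 2, 0.15)
    graph = build_graph(strings, 5)
    eulerise(graph, greedy_plan(graph))
    seen = Counter()
    for comp in graph.connected_components():
        if not any(graph.out_arcs(v) for v in comp):
            continue
        circuit = bi_eulerian_circuit(graph, comp)
        for aid in circuit:
            seen[min(aid, graph.arcs[aid].twin)] += 1
    assert set(seen) == set(graph.iter_biarcs())
    assert all(c == 1 for c in seen.values())


def test_circuit_rejects_unbalanced_graph():
    graph = build_graph(["ACCTC"], 4)
    with pytest.raises(GraphError):
        bi_eulerian_circuit(graph)


def _toy_circuit_graph():
    """A hand-built balanced doubled graph for break_circuit unit tests."""
    graph = BidirectedDbg(4)
    a = graph.add_original_biarc("AACCA")
    b = graph.add_original_biarc("CCAAC")
    return graph, a, b


def test_break_at_all_breaking_biarcs():
    graph, a, b = _toy_circuit_graph()
    na, nc = graph.arcs[a].tail, graph.arcs[a].head
    b1 = graph.add_breaking_biarc(nc, nc)
    b2 = graph.add_breaking_biarc(na, na)
    circuit = Biwalk([a, b1, b, b2])
    walks = break_circuit(circuit, graph)
    assert len(walks) == 2
    assert [w.arcs for w in walks] == [[b], [a]]


def test_break_at_longest_dummy_first_on_ties():
    graph, a, b = _toy_circuit_graph()
    na, nc = graph.arcs[a].tail, graph.arcs[a].head
    d1 = graph.add_dummy_biarc(nc, nc, 1)
    d3 = graph.add_dummy_biarc(na, na, 3)
    d2 = graph.add_dummy_biarc(nc, nc, 2)
    # circular walk with dummy lengths 1, 3, 2 and no breaking biarcs
    circuit = Biwalk([a, d1, b, d3, a, d2, b])
    walks = break_circuit(circuit, graph)
    assert len(walks) == 1
    assert walks[0].arcs == [a, d2, b, a, d1, b]  # cut right after the 3-dummy


def test_pure_cycle_opens_at_smallest_arc_id():
    graph, a, b = _toy_circuit_graph()
    circuit = Biwalk([b, a])
    walks = break_circuit(circuit, graph)
    assert len(walks) == 1
    assert walks[0].arcs[0] == min(a, b)


def test_break_empty_circuit_rejected():
    graph, _, _ = _toy_circuit_graph()
    with pytest.raises(GraphError):
        break_circuit(Biwalk([]), graph)
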