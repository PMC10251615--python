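import random

import networkx as nx
import pytest

from tigkit.balance import classify, many_to_many_paths
from tigkit.graph import ORIGINAL, build_graph
from tigkit.matching import (
    U_NODE,
    W_NODE,
    EulerisationPlan,
    FlowModel,
    MatchingError,
    build_matching_graph,
    eulertigs_plan,
    interpret_matching,
    matching_cost,
    reduce_to_perfect,
    solve_perfect_matching,
)
from tigkit.eulertour import eulerise
from tigkit.fixtures import (
    brute_force_matching,
    brute_force_min_spss,
    random_genome,
    random_pangenome,
)
from tigkit import dna


def _pipeline_pieces(strings, k):
    graph = build_graph(strings, k)
    table = classify(graph)
    paths = many_to_many_paths(graph, table)
    return graph, table, paths


def test_matching_graph_structure_single_pair():
    # one source unit, one sink unit, one connecting path: the matching graph
    # has the two copies plus u and w, one path edge and four forcing edges
    graph, table, paths = _pipeline_pieces(["GCATGCATG"], 5)
    assert sum(d.units for d in table.demands.values()) == 2
    assert len(paths) == 1
    m = build_matching_graph(table, paths, graph.k)
    assert len(m.copies) == 2
    path_edges = [e for e in m.edges if U_NODE not in e[:2] and W_NODE not in e[:2]]
    forcing = [e for e in m.edges if U_NODE in e[:2] or W_NODE in e[:2]]
    assert len(path_edges) == 1
    assert len(forcing) == 4
    assert all(cost == 0 for *_, cost in forcing)


def test_copies_follow_absolute_imbalance():
    # a binode with |bi| = 2 gets two copies in the matching graph
    graph, table, paths = _pipeline_pieces(
        ["GCTCAT", "GCTATA", "ACGTTA"], 4
    )
    rep = next(r for r, d in table.demands.items()
               if abs(d.bi) == 2 and not d.self_complemental)
    m = build_matching_graph(table, paths, graph.k)
    assert sum(1 for c in m.copies if c[0] == rep) == 2


def test_bieulerian_input_signals_skip():
    graph = build_graph(["AAGGCAAG"], 4)
    table = classify(graph)
    with pytest.raises(MatchingError):
        build_matching_graph(table, many_to_many_paths(graph, table), graph.k)


def test_perfect_reduction_u_and_w_have_no_copy_edge():
    graph, table, paths = _pipeline_pieces(["GCATGCATG"], 5)
    m = build_matching_graph(table, paths, graph.k)
    inst = reduce_to_perfect(m, graph.k)
    assert not inst.has_edge((U_NODE, 0), (U_NODE, 1))
    assert not inst.has_edge((W_NODE, 0), (W_NODE, 1))
    for c in m.copies:
        assert inst.edges[(c, 0), (c, 1)]["weight"] == graph.k - 1
    # u is forced into a zero-cost edge in any perfect matching
    sol = solve_perfect_matching(inst)
    partner = {a: b for pair in sol for a, b in
               [tuple(pair), tuple(pair)[::-1]]}
    assert inst.edges[(U_NODE, 0), partner[(U_NODE, 0)]]["weight"] == 0


def test_isolated_copies_cost_k_minus_1_each_beyond_u_w():
    # no paths at all: perfect matching must use node-copy edges for all but
    # the two copies taken by u and w
    graph = build_graph(["CCTTAA", "GGGGCT"], 4)
    table = classify(graph)
    paths = many_to_many_paths(graph, table)
    assert len(paths) == 0
    m = build_matching_graph(table, paths, graph.k)
    inst = reduce_to_perfect(m, graph.k)
    sol = solve_perfect_matching(inst)
    n = len(m.copies)
    assert matching_cost(inst, sol) == (graph.k - 1) * (n - 2)
    assert matching_cost(inst, sol) == brute_force_matching(inst)


def test_cheap_path_edge_preferred_over_unmatched():
    graph, table, paths = _pipeline_pieces(["GCATGCATG"], 5)
    entry = next(iter(paths.entries.values()))
    assert entry.cost < graph.k - 1
    m = build_matching_graph(table, paths, graph.k)
    inst = reduce_to_perfect(m, graph.k)
    sol = solve_perfect_matching(inst)
    assert matching_cost(inst, sol) == brute_force_matching(inst)
    plan = interpret_matching(sol, table, paths, graph.k)
    assert len(plan.joining) == 0 or plan.joining[0][2] == entry.cost


@pytest.mark.parametrize("trial", range(100))
def test_solver_matches_bruteforce_on_random_instances(trial):
    rng = random.Random(trial)
    n = rng.choice([4, 6, 8, 10])
    g = nx.Graph()
    g.add_nodes_from(range(n))
    perm = list(range(n))
    rng.shuffle(perm)
    for i in range(0, n, 2):  # guarantee a perfect matching exists
        g.add_edge(perm[i], perm[i + 1], weight=rng.randint(0, 20))
    for _ in range(rng.randint(0, 2 * n)):
        a, b = rng.sample(range(n), 2)
        if not g.has_edge(a, b):
            g.add_edge(a, b, weight=rng.randint(0, 20))
    sol = solve_perfect_matching(g)
    assert matching_cost(g, sol) == brute_force_matching(g)


def test_k4_matching_minimum():
    g = nx.Graph()
    costs = {(0, 1): 3, (2, 3): 4, (0, 2): 1, (1, 3): 2, (0, 3): 10, (1, 2): 10}
    for (a, b), c in costs.items():
        g.add_edge(a, b, weight=c)
    assert brute_force_matching(g) == 3  # {0-2, 1-3}
    assert matching_cost(g, solve_perfect_matching(g)) == 3


def _matchtigs_plan(strings, k):
    graph, table, paths = _pipeline_pieces(strings, k)
    if table.is_bi_eulerian:
        return graph, table, EulerisationPlan()
    m = build_matching_graph(table, paths, k)
    inst = reduce_to_perfect(m, k)
    plan = interpret_matching(solve_perfect_matching(inst), table, paths, k)
    return graph, table, plan


@pytest.mark.parametrize("seed", range(20))
def test_interpreted_plan_balances_graph_and_has_breaking_arc(seed):
    strings = [random_genome(seed, 25)]
    graph, table, plan = _matchtigs_plan(strings, 5)
    if not table.is_bi_eulerian:
        assert len(plan.breaking) >= 1
        FlowModel(graph, plan).check()
        eulerise(graph, plan)  # raises if the plan does not balance


def test_plan_cost_invariant_under_unmatched_pairing():
    # any pairing of unmatched copies costs the same: (k-1) per pair
    graph = build_graph(["CCTTAA", "GGGGCT"], 4)
    table = classify(graph)
    plan = eulertigs_plan(table)
    n_units = sum(d.units for d in table.demands.values())
    assert plan.total_cost(graph.k) == (graph.k - 1) * (n_units // 2)


@pytest.mark.parametrize("seed", range(30))
def test_plan_cost_equals_min_flow_objective_on_small_graphs(seed):
    """On graphs of <= 6 binodes the plan cost must hit the flow optimum.

    The minimum feasible flow objective equals (min SPSS size) minus the
    characters of the original biarcs, by the walk-size identity; the
    brute-force SPSS search provides that minimum independently.
    """
    genome = random_genome(1000 + seed, 14)
    graph, table, plan = _matchtigs_plan([genome], 5)
    if len(graph.binode_reps()) > 6 or table.is_bi_eulerian:
        return
    FlowModel(graph, plan).check()
    orig_cost = sum(
        graph.arcs[a].cost for a in graph.iter_biarcs(ORIGINAL)
    )
    oracle_cl, _ = brute_force_min_spss(
        dna.spectrum([genome], 5), 5, allow_repeats=True
    )
    assert plan.total_cost(graph.k) == oracle_cl - orig_cost


def test_flow_model_rejects_plan_without_breaking_arc():
    graph, table, plan = _matchtigs_plan(["GCATGCATG"], 5)
    bad = EulerisationPlan(joining=list(plan.joining), breaking=[])
    with pytest.raises(MatchingError):
        FlowModel(graph, bad).check()
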