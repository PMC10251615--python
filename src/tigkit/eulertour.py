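"""Eulerisation, biEulerian circuits and circuit breaking.

A biEulerian circuit visits every biarc exactly once: traversing an arc
consumes its twin simultaneously (a self-complemental biarc consumes its
single arc).  Circuits are computed per connected component with a
Hierholzer-style edge-consumption walk; the next arc out of a node is always
the unused one with the smallest id, so circuits are deterministic.
"""

from __future__ import annotations

from .balance import bi_imbalance, capped_min_cost_paths, classify
from .graph import BREAKING, DUMMY, ORIGINAL, BidirectedDbg, Biwalk, GraphError
from .matching import EulerisationPlan


def _verify_balanced(graph: BidirectedDbg) -> None:
    for rep in graph.binode_reps():
        node = graph.nodes[rep]
        value = bi_imbalance(graph, rep, kinds="all")
        if node.is_self_complemental:
            if value % 2 != 0:
                raise GraphError(f"odd parity at self-complemental node {rep}")
        elif value != 0:
            raise GraphError(f"bi-imbalance {value} at node {rep} after plan")


def eulerise(graph: BidirectedDbg, plan: EulerisationPlan) -> BidirectedDbg:
    """Insert the plan's dummy and breaking biarcs (with twins) into the graph.

    If the plan is empty the graph must already be biEulerian; one breaking
    biarc (a loop pair at the smallest node id of each component) is then
    inserted so the circuit remains breakable.  A plan that does not balance
    the graph is a contract violation.
    """
    if not plan.joining and not plan.breaking:
        table = classify(graph)
        if not table.is_bi_eulerian:
            raise GraphError("empty plan on a graph that is not biEulerian")
        for comp in graph.connected_components():
            with_arcs = [v for v in comp if graph.out_arcs(v) or graph.in_arcs(v)]
            if with_arcs:
                v = min(with_arcs)
                graph.add_breaking_biarc(v, v)
        _verify_balanced(graph)
        return graph
    for tail, head, length in plan.joining:
        graph.add_dummy_biarc(tail, head, length)
    for tail, head in plan.breaking:
        graph.add_breaking_biarc(tail, head)
    _verify_balanced(graph)
    return graph


def greedy_plan(graph: BidirectedDbg, cap: int | None = None) -> EulerisationPlan:
    """Greedy Eulerisation: nearest capped sinks first, breaking arcs last.

    Unbalanced binodes are processed in id order.  For each one a capped
    min-cost search runs from its negative orientation and dummy arcs are
    committed to the nearest other binodes with remaining demand (ties by
    binode id) until its demand is met or no sink within the cap remains;
    joins are made whenever they do not increase CL, including at cost exactly
    k-1.  Leftover demand is fixed with breaking arcs.  Single-worker
    processing in ascending id order is the reference schedule; commits touch
    demands of both endpoints, so any concurrent schedule must serialise
    per-binode updates in the same global order to produce identical plans.
    """
    if cap is None:
        cap = graph.k - 1
    table = classify(graph)
    demand = {rep: d.units for rep, d in table.demands.items()}
    sink_of = {d.pos: rep for rep, d in table.demands.items()}
    plan = EulerisationPlan()

    for rep in sorted(demand):
        if demand[rep] == 0:
            continue
        d = table.demands[rep]
        candidates = []
        for node, cost in capped_min_cost_paths(graph, d.neg, cap):
            other = sink_of.get(node)
            if other is None or node == d.neg:
                continue
            if other == rep and d.self_complemental:
                continue
            candidates.append((cost, other, node))
        candidates.sort()
        for cost, other, node in candidates:
            if demand[rep] == 0:
                break
            if other == rep:
                if demand[rep] >= 2:
                    plan.joining.append((d.neg, node, cost))
                    demand[rep] -= 2
            elif demand[other] > 0:
                plan.joining.append((d.neg, node, cost))
                demand[rep] -= 1
                demand[other] -= 1

    leftovers = [
        (rep, i) for rep in sorted(demand) for i in range(demand[rep])
    ]
    for first, second in zip(leftovers[::2], leftovers[1::2]):
        plan.breaking.append(
            (table.demands[first[0]].neg, table.demands[second[0]].pos)
        )
    return plan


def greedy_eulerise(graph: BidirectedDbg, cap: int | None = None) -> BidirectedDbg:
    """Apply the greedy plan to the graph (see :func:`greedy_plan`)."""
    plan = greedy_plan(graph, cap)
    return eulerise(graph, plan)


def bi_eulerian_circuit(
    graph: BidirectedDbg, component: list[int] | None = None
) -> Biwalk:
    """A circular biwalk using each biarc of the component exactly once.

    At self-complemental nodes incident biarcs are paired as the traversal
    encounters them; every biarc is still used exactly once because consuming
    an arc always consumes its twin.  Raises on unbalanced or disconnected
    input (every arc of the component must be reachable).
    """
    nodes = component if component is not None else [n.id for n in graph.nodes]
    node_set = set(nodes)
    todo = {
        a.id
        for a in graph.arcs
        if a.tail in node_set
    }
    if not todo:
        raise GraphError("component has no arcs")
    used = [False] * len(graph.arcs)
    out_idx = {v: 0 for v in nodes}
    start = min(v for v in nodes if graph.out_arcs(v))

    vstack: list[int] = [start]
    estack: list[int] = []
    result: list[int] = []
    while vstack:
        v = vstack[-1]
        outs = graph.out_arcs(v)
        idx = out_idx[v]
        chosen = None
        while idx < len(outs):
            if not used[outs[idx]]:
                chosen = outs[idx]
                break
            idx += 1
        out_idx[v] = idx
        if chosen is None:
            vstack.pop()
            if estack:
                result.append(estack.pop())
        else:
            arc = graph.arcs[chosen]
            used[chosen] = True
            used[arc.twin] = True
            estack.append(chosen)
            vstack.append(arc.head)
    result.reverse()
    covered = set()
    for aid in result:
        covered.add(aid)
        covered.add(graph.arcs[aid].twin)
    if covered != todo:
        raise GraphError(
            "graph is not biEulerian on this component "
            "(unbalanced or disconnected)"
        )
    if graph.arcs[result[-1]].head != graph.arcs[result[0]].tail:
        raise GraphError("graph is not biEulerian: walk is not circular")
    for prev, cur in zip(result, result[1:]):
        if graph.arcs[prev].head != graph.arcs[cur].tail:
            raise GraphError("internal error: circuit not consecutive")
    return Biwalk(result)


def break_circuit(circuit: Biwalk, graph: BidirectedDbg) -> list[Biwalk]:
    """Cut a circular biwalk into the walks that spell the output strings.

    If the circuit contains breaking biarcs it is split at all of them and
    they are discarded (one walk per breaking biarc).  Otherwise, if it
    contains dummy biarcs, it is split at one longest dummy (first
    encountered on ties), which removes the most repeated characters.
    Otherwise the pure cycle is opened at the biarc with the smallest arc id.
    """
    arcs = list(circuit.arcs)
    if not arcs:
        raise GraphError("cannot break an empty circuit")
    kinds = [graph.arcs[a].kind for a in arcs]
    break_positions = [i for i, kind in enumerate(kinds) if kind == BREAKING]
    if break_positions:
        walks = []
        n = len(arcs)
        for j, pos in enumerate(break_positions):
            nxt = break_positions[(j + 1) % len(break_positions)]
            segment = []
            i = (pos + 1) % n
            while i != nxt:
                segment.append(arcs[i])
                i = (i + 1) % n
            if segment:
                walks.append(Biwalk(segment))
        return walks
    dummies = [
        (graph.arcs[a].dummy_len, i)
        for i, a in enumerate(arcs)
        if graph.arcs[a].kind == DUMMY
    ]
    if dummies:
        longest = max(length for length, _ in dummies)
        cut = next(i for length, i in dummies if length == longest)
        return [Biwalk(arcs[cut + 1 :] + arcs[:cut])]
    smallest = arcs.index(min(arcs))
    return [Biwalk(arcs[smallest:] + arcs[:smallest])]
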