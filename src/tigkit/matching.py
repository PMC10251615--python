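"""Min-cost matching of Eulerisation demands.

Every unbalanced binode enters an undirected matching graph with |bi_v| copies
(odd-parity self-complemental binodes with one copy).  Edges between copies of
two binodes carry the cost of the min-cost connection between them (from the
capped path search); matching such an edge joins two strings by repeating the
k-mers along the path.  A node left unmatched costs (k-1)/2, because every
*pair* of unmatched nodes is fixed with one breaking arc of cost k-1.  A
forcing pair {u, w} with zero-cost edges to every copy (and no u-w edge)
guarantees at least two copies stay unmatched, hence at least one breaking
biarc — the final circular walk must be breakable somewhere.

The penalised problem reduces to min-cost *perfect* matching by duplicating
the graph and connecting each copy to its duplicate with an edge of cost k-1
(u, w and their duplicates get none).  All costs are integers, so no scaling
is needed.  The exact blossom solver behind ``networkx.min_weight_matching``
computes the optimum; a brute-force enumeration oracle cross-checks it in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .balance import ImbalanceTable, PathTable
from .graph import BREAKING, DUMMY, ORIGINAL, BidirectedDbg
from . import balance as _balance

U_NODE = "u"
W_NODE = "w"


class MatchingError(ValueError):
    pass


@dataclass
class MatchingGraph:
    """Penalised matching graph M (twin-merged copies plus the u/w gadget)."""

    copies: list[tuple[int, int]]  # (binode rep, copy index)
    edges: list[tuple[object, object, int]]  # path edges + zero-cost u/w edges
    k: int

    @property
    def unmatched_penalty(self) -> float:
        return (self.k - 1) / 2


@dataclass
class EulerisationPlan:
    """Arc insertions that balance the graph.

    ``joining``: (tail node, head node, dummy length) triples; ``breaking``:
    (tail node, head node) pairs.  Applying the plan makes every bi-imbalance
    zero and every self-complemental parity even.
    """

    joining: list[tuple[int, int, int]] = field(default_factory=list)
    breaking: list[tuple[int, int]] = field(default_factory=list)

    def total_cost(self, k: int) -> int:
        return sum(l for _, _, l in self.joining) + (k - 1) * len(self.breaking)


def build_matching_graph(
    table: ImbalanceTable, paths: PathTable, k: int
) -> MatchingGraph:
    """Build M from the demand classification and the path table."""
    if table.is_bi_eulerian:
        raise MatchingError(
            "graph is biEulerian: skip matching and insert one breaking biarc"
        )
    copies: list[tuple[int, int]] = []
    copies_of: dict[int, list[tuple[int, int]]] = {}
    for rep in sorted(table.demands):
        these = [(rep, i) for i in range(table.demands[rep].units)]
        copies.extend(these)
        copies_of[rep] = these

    edges: list[tuple[object, object, int]] = []
    for (ra, rb), entry in sorted(paths.entries.items()):
        if ra == rb:
            # joins two copies of the same binode via a self-complemental
            # connection; needs at least two copies
            group = copies_of[ra]
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    edges.append((group[i], group[j], entry.cost))
        else:
            for a in copies_of[ra]:
                for b in copies_of[rb]:
                    edges.append((a, b, entry.cost))
    for c in copies:
        edges.append((U_NODE, c, 0))
        edges.append((W_NODE, c, 0))
    return MatchingGraph(copies, edges, k)


def reduce_to_perfect(m: MatchingGraph, k: int) -> nx.Graph:
    """Duplicate M and add cost-(k-1) edges between each copy and its duplicate."""
    g = nx.Graph()
    for half in (0, 1):
        for node in [U_NODE, W_NODE] + m.copies:
            g.add_node((node, half))
        for a, b, cost in m.edges:
            g.add_edge((a, half), (b, half), weight=cost)
    for c in m.copies:
        g.add_edge((c, 0), (c, 1), weight=k - 1)
    return g


def solve_perfect_matching(instance: nx.Graph) -> set[frozenset]:
    """Minimum-cost perfect matching of the doubled instance (exact blossom)."""
    matching = nx.min_weight_matching(instance, weight="weight")
    matched = {n for pair in matching for n in pair}
    if matched != set(instance.nodes):
        raise MatchingError("instance admits no perfect matching")
    return {frozenset(pair) for pair in matching}


def matching_cost(instance: nx.Graph, solution: set[frozenset]) -> int:
    return sum(instance.edges[tuple(pair)]["weight"] for pair in solution)


def interpret_matching(
    solution: set[frozenset],
    table: ImbalanceTable,
    paths: PathTable,
    k: int,
) -> EulerisationPlan:
    """Translate the original half of the perfect matching into a plan.

    Path edges become joining (dummy) arcs oriented from the negative
    orientation of one binode to the positive orientation of the other.
    Copies matched to their duplicate or to u/w stay unmatched; they are
    paired off in sorted order into breaking arcs — any pairing costs the
    same.  The u/w gadget guarantees at least one breaking biarc.
    """
    partner: dict[object, object] = {}
    for pair in solution:
        a, b = tuple(pair)
        partner[a] = b
        partner[b] = a

    plan = EulerisationPlan()
    unmatched: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for copy in sorted(c for c in partner if isinstance(c, tuple)
                       and c[1] == 0 and isinstance(c[0], tuple)):
        c = copy[0]
        if c in seen:
            continue
        mate = partner[copy]
        if mate == (c, 1) or mate[0] in (U_NODE, W_NODE):
            unmatched.append(c)
            seen.add(c)
            continue
        other = mate[0]
        seen.add(c)
        seen.add(other)
        key = (min(c[0], other[0]), max(c[0], other[0]))
        entry = paths.entries[key]
        plan.joining.append((entry.tail, entry.head, entry.cost))

    if len(unmatched) % 2 != 0:
        raise MatchingError("odd number of unmatched copies")
    if not unmatched:
        raise MatchingError("u/w gadget failed to force a breaking biarc")
    unmatched.sort()
    for first, second in zip(unmatched[::2], unmatched[1::2]):
        tail = table.demands[first[0]].neg
        head = table.demands[second[0]].pos
        plan.breaking.append((tail, head))
    return plan


def eulertigs_plan(table: ImbalanceTable) -> EulerisationPlan:
    """The breaking-arcs-only plan: every demand unit fixed without repeats."""
    plan = EulerisationPlan()
    units = [
        (rep, i)
        for rep in sorted(table.demands)
        for i in range(table.demands[rep].units)
    ]
    for first, second in zip(units[::2], units[1::2]):
        plan.breaking.append(
            (table.demands[first[0]].neg, table.demands[second[0]].pos)
        )
    return plan


class FlowModel:
    """Feasibility checker for the min-cost integer flow formulation.

    A plan induces a flow: each joining arc carries one unit between its
    endpoints (standing for one unit on every original arc of its path), each
    breaking arc one unit on an inserted breaking arc.  The checker verifies
    by substitution: non-negative integrality, at least one breaking arc
    covered, the bidirected balance constraint at every non-self-complemental
    node, the parity constraint at every self-complemental node, and twin
    symmetry (inserted biarcs are twin pairs by construction).
    """

    def __init__(self, graph: BidirectedDbg, plan: EulerisationPlan) -> None:
        self.graph = graph
        self.plan = plan

    def check(self) -> None:
        graph, plan = self.graph, self.plan
        for _, _, length in plan.joining:
            if not (isinstance(length, int) and 1 <= length <= graph.k - 1):
                raise MatchingError(f"invalid joining length {length}")
        if not plan.breaking:
            raise MatchingError("flow must cover at least one breaking arc")
        inserted_out: dict[int, int] = {}
        inserted_in: dict[int, int] = {}

        def add(tail: int, head: int) -> None:
            # one unit on the arc and one on its twin
            for t, h in ((tail, head),
                         (graph.nodes[head].twin, graph.nodes[tail].twin)):
                inserted_out[t] = inserted_out.get(t, 0) + 1
                inserted_in[h] = inserted_in.get(h, 0) + 1

        for tail, head, _ in plan.joining:
            add(tail, head)
        for tail, head in plan.breaking:
            add(tail, head)

        for rep in graph.binode_reps():
            node = graph.nodes[rep]
            demand = _balance.bi_imbalance(graph, rep)
            if node.is_self_complemental:
                if (demand + inserted_out.get(rep, 0)) % 2 != 0:
                    raise MatchingError(f"parity violated at node {rep}")
            else:
                got = inserted_in.get(rep, 0) - inserted_out.get(rep, 0)
                if got != demand:
                    raise MatchingError(
                        f"balance violated at node {rep}: flow {got}, "
                        f"demand {demand}"
                    )
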