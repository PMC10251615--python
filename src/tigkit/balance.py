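"""Bi-imbalances, source/sink classification and capped min-cost path search.

The Eulerisation demand of every binode is its *bi-imbalance*.  For a binode
[v, v^-1] with v != v^-1 it is

    bi_v = d_F+(v) - d_F-(v) + [ (v,v^-1) in F+(v) ] - [ (v^-1,v) in F-(v) ]

with degrees restricted to the covered (original) arc set F; the indicator
terms account for self-complemental biarcs, which alter the balance by two.
For a self-complemental binode [v] there is no in/out distinction and only the
parity matters:  bi_v = d_F+(v) mod 2.

A binode with bi_v < 0 at a node v is missing outgoing cover at v (joining or
breaking arcs must *leave* v) and symmetrically its twin orientation is
missing incoming cover.  Min-cost paths are searched from the negative
orientation of every unbalanced binode (and from every odd-parity
self-complemental binode) to the positive orientations, capped at cost k-1:
longer connections can never beat simply starting a new string.
"""

from __future__ import annotations

import heapq
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .graph import ORIGINAL, BidirectedDbg

#: Number of Dijkstra sources handed to a worker at a time.  Purely a work
#: partitioning knob: results are a pure function of the graph.
DEFAULT_BLOCK_SIZE = 64


@dataclass
class BinodeDemand:
    """Eulerisation demand of one unbalanced (or odd-parity) binode."""

    rep: int  # representative node id (min of the twin pair)
    bi: int  # bi-imbalance evaluated at rep (parity for self-complemental)
    self_complemental: bool
    units: int  # |bi|, the number of matching copies
    neg: int  # node where added arcs must leave (tail role)
    pos: int  # node where added arcs must enter (head role)


@dataclass
class ImbalanceTable:
    """Classification of all binodes by bi-imbalance."""

    bi: dict[int, int]  # representative node id -> bi-imbalance at that node
    sources: list[int]  # A: representatives with bi < 0
    sinks: list[int]  # B: representatives with bi > 0
    self_complemental: list[int]  # S: all self-complemental binodes
    demands: dict[int, BinodeDemand]  # unbalanced T + odd-parity S only

    @property
    def is_bi_eulerian(self) -> bool:
        return not self.demands


def bi_imbalance(graph: BidirectedDbg, node: int, kinds: str = "original") -> int:
    """Bi-imbalance of the binode of *node*, evaluated at *node*.

    ``kinds='original'`` restricts degrees to the covered arc set F (the
    classification used before Eulerisation); ``kinds='all'`` includes
    inserted arcs (used to verify a Eulerised graph is balanced).
    """
    if not 0 <= node < len(graph.nodes):
        raise KeyError(f"unknown node id {node}")

    def keep(aid: int) -> bool:
        return kinds == "all" or graph.arcs[aid].kind == ORIGINAL

    n = graph.nodes[node]
    outs = [a for a in graph.out_arcs(node) if keep(a)]
    if n.is_self_complemental:
        return len(outs) % 2
    ins = [a for a in graph.in_arcs(node) if keep(a)]
    self_out = any(graph.arcs[a].is_self_complemental for a in outs)
    self_in = any(graph.arcs[a].is_self_complemental for a in ins)
    return len(outs) - len(ins) + int(self_out) - int(self_in)


def classify(graph: BidirectedDbg) -> ImbalanceTable:
    """Compute bi-imbalances of all binodes and the Eulerisation demands."""
    bi: dict[int, int] = {}
    sources: list[int] = []
    sinks: list[int] = []
    self_comp: list[int] = []
    demands: dict[int, BinodeDemand] = {}
    for rep in graph.binode_reps():
        node = graph.nodes[rep]
        value = bi_imbalance(graph, rep)
        bi[rep] = value
        if node.is_self_complemental:
            self_comp.append(rep)
            if value % 2 == 1:
                demands[rep] = BinodeDemand(rep, value, True, 1, rep, rep)
            continue
        if value < 0:
            sources.append(rep)
            demands[rep] = BinodeDemand(rep, value, False, -value, rep, node.twin)
        elif value > 0:
            sinks.append(rep)
            demands[rep] = BinodeDemand(rep, value, False, value, node.twin, rep)
    total_units = sum(d.units for d in demands.values())
    if total_units % 2 != 0:  # impossible for a well-formed bidirected graph
        raise AssertionError("odd total Eulerisation demand")
    return ImbalanceTable(bi, sources, sinks, self_comp, demands)


def capped_min_cost_paths(
    graph: BidirectedDbg, source: int, cap: int
) -> list[tuple[int, int]]:
    """Min-cost distances along original biarcs from *source*, capped at *cap*.

    Returns (node, cost) pairs with 0 < cost <= cap, sorted by (cost, node).
    The search frontier is abandoned as soon as the tentative cost exceeds the
    cap, and distances live in a sparse map keyed by node id.  Ties in the
    priority queue break on node id, so traversal order is deterministic.
    """
    dist: dict[int, int] = {source: 0}
    heap: list[tuple[int, int]] = [(0, source)]
    while heap:
        cost, node = heapq.heappop(heap)
        if cost > cap:
            break
        if cost > dist.get(node, cost):
            continue
        for aid in graph.out_arcs(node):
            arc = graph.arcs[aid]
            if arc.kind != ORIGINAL:
                continue
            nxt = cost + arc.cost
            if nxt <= cap and nxt < dist.get(arc.head, nxt + 1):
                dist[arc.head] = nxt
                heapq.heappush(heap, (nxt, arc.head))
    return sorted((n, c) for n, c in dist.items() if c > 0)


@dataclass
class PathEntry:
    """A min-cost connection between two unbalanced binodes."""

    source_rep: int
    sink_rep: int
    cost: int
    tail: int  # node the joining arc leaves
    head: int  # node the joining arc enters


@dataclass
class PathTable:
    """Min-cost connections of cost <= k-1, one per unordered binode pair."""

    entries: dict[tuple[int, int], PathEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def many_to_many_paths(
    graph: BidirectedDbg,
    table: ImbalanceTable,
    cap: int | None = None,
    threads: int = 1,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> PathTable:
    """Capped searches from every source orientation, merged into a PathTable.

    Entries connect the negative orientation of one demand to the positive
    orientation of another (self-loops at self-complemental binodes are
    ignored; a connection between the two orientations of the *same*
    non-self-complemental binode is kept, it joins two of its copies).  The
    result is a pure function of the graph: sources are processed in blocks,
    possibly by several workers, and merged deterministically.
    """
    if cap is None:
        cap = graph.k - 1
    demands = table.demands
    sink_of: dict[int, int] = {d.pos: rep for rep, d in demands.items()}

    sources = sorted(demands)

    def search_block(block: list[int]) -> list[PathEntry]:
        found = []
        for rep in block:
            demand = demands[rep]
            for node, cost in capped_min_cost_paths(graph, demand.neg, cap):
                other = sink_of.get(node)
                if other is None or node == demand.neg:
                    continue
                if other == rep and demand.self_complemental:
                    continue  # parity-neutral self loop
                found.append(PathEntry(rep, other, cost, demand.neg, node))
        return found

    blocks = [sources[i : i + block_size] for i in range(0, len(sources), block_size)]
    if threads > 1 and len(blocks) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(search_block, blocks))
    else:
        results = [search_block(b) for b in blocks]

    out = PathTable()
    all_entries = [e for block in results for e in block]
    all_entries.sort(key=lambda e: (e.cost, e.source_rep, e.sink_rep))
    for entry in all_entries:
        key = (min(entry.source_rep, entry.sink_rep),
               max(entry.source_rep, entry.sink_rep))
        if key not in out.entries:
            out.entries[key] = entry
    return out
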