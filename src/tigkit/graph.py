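"""Compacted bidirected arc-centric de Bruijn graphs.

The graph is stored as a *doubled* directed graph: every (k-1)-mer overlap is
a node and has a twin node holding its reverse complement (a *binode*), and
every maximal unitig is an arc paired with a twin arc spelling its reverse
complement (a *biarc*).  A node or arc whose label equals its own reverse
complement is *self-complemental* and is its own twin; for DNA this can happen
only for odd k (nodes) or even k (arcs), never both.

Arc costs equal the number of k-mers an arc represents, i.e. |label| - (k-1),
so the cost of a walk counts one character per uncompacted arc.  Besides the
``original`` unitig arcs the graph can hold two kinds of inserted arcs used by
the Eulerisation machinery:

* ``dummy`` (joining) arcs stand for a min-cost path of total cost l between
  two nodes; they carry no label and are spelled by appending the last l
  characters of their head node's (k-1)-mer.
* ``breaking`` arcs mark where the final circular walk is cut; they cost k-1
  and are never spelled.

Inserted biarcs are always twin *pairs* of arc objects (two parallel arcs when
the biarc would be self-complemental), which keeps the balance bookkeeping for
inserted arcs free of self-complementality special cases.  Original palindromic
k-mers remain genuine single self-complemental arcs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import dna
from .spss import Spss

ORIGINAL = "original"
BREAKING = "breaking"
DUMMY = "dummy"


class GraphError(ValueError):
    pass


class SequenceStore:
    """Append-only shared buffer for arc labels.

    Labels are referenced as (offset, length, forward) triples; the reverse
    orientation is materialised on demand.  Two-bit packing would slot in here
    without touching any caller.
    """

    def __init__(self) -> None:
        self._chunks: list[str] = []
        self._length = 0
        self._buffer: str | None = None

    def add(self, s: str) -> int:
        offset = self._length
        self._chunks.append(s)
        self._length += len(s)
        self._buffer = None
        return offset

    def get(self, offset: int, length: int, forward: bool = True) -> str:
        if self._buffer is None:
            self._buffer = "".join(self._chunks)
        s = self._buffer[offset : offset + length]
        return s if forward else dna._rc_unchecked(s)


@dataclass
class Node:
    id: int
    label: str  # the (k-1)-mer
    twin: int

    @property
    def is_self_complemental(self) -> bool:
        return self.twin == self.id


@dataclass
class Arc:
    id: int
    tail: int
    head: int
    kind: str
    cost: int
    twin: int
    offset: int = -1  # into the sequence store; original arcs only
    length: int = 0
    forward: bool = True
    dummy_len: int = 0

    @property
    def is_self_complemental(self) -> bool:
        return self.twin == self.id


@dataclass
class Biwalk:
    """A sequence of consecutive biarcs, each given by one of its arc ids."""

    arcs: list[int]

    def __len__(self) -> int:
        return len(self.arcs)

    def __iter__(self):
        return iter(self.arcs)


class BidirectedDbg:
    """Doubled-graph representation of a compacted bidirected de Bruijn graph."""

    def __init__(self, k: int) -> None:
        if k < 2:
            raise GraphError(f"k must be >= 2, got {k}")
        self.k = k
        self.nodes: list[Node] = []
        self.arcs: list[Arc] = []
        self.node_lookup: dict[str, int] = {}
        self.store = SequenceStore()
        self._out: list[list[int]] = []
        self._in: list[list[int]] = []

    # -- construction -----------------------------------------------------

    def add_binode(self, km1: str) -> int:
        """Insert the binode for a (k-1)-mer (and its twin); return its node id."""
        existing = self.node_lookup.get(km1)
        if existing is not None:
            return existing
        rc = dna._rc_unchecked(km1)
        nid = len(self.nodes)
        if rc == km1:
            self.nodes.append(Node(nid, km1, nid))
            self.node_lookup[km1] = nid
            self._out.append([])
            self._in.append([])
        else:
            self.nodes.append(Node(nid, km1, nid + 1))
            self.nodes.append(Node(nid + 1, rc, nid))
            self.node_lookup[km1] = nid
            self.node_lookup[rc] = nid + 1
            self._out.append([])
            self._out.append([])
            self._in.append([])
            self._in.append([])
        return nid

    def _register_arc(self, arc: Arc) -> None:
        self.arcs.append(arc)
        self._out[arc.tail].append(arc.id)
        self._in[arc.head].append(arc.id)

    def add_original_biarc(self, label: str) -> int:
        """Insert a unitig as a biarc; returns the forward arc id."""
        km1 = self.k - 1
        if len(label) < self.k:
            raise GraphError(f"arc label shorter than k: {label!r}")
        tail = self.node_lookup.get(label[:km1])
        if tail is None:
            tail = self.add_binode(label[:km1])
        head = self.node_lookup.get(label[-km1:])
        if head is None:
            head = self.add_binode(label[-km1:])
        cost = len(label) - km1
        offset = self.store.add(label)
        aid = len(self.arcs)
        if dna.is_self_complemental(label):
            self._register_arc(
                Arc(aid, tail, head, ORIGINAL, cost, aid, offset, len(label), True)
            )
        else:
            rc_tail = self.nodes[head].twin
            rc_head = self.nodes[tail].twin
            self._register_arc(
                Arc(aid, tail, head, ORIGINAL, cost, aid + 1, offset, len(label), True)
            )
            self._register_arc(
                Arc(
                    aid + 1, rc_tail, rc_head, ORIGINAL, cost, aid,
                    offset, len(label), False,
                )
            )
        return aid

    def _add_inserted_pair(self, tail: int, head: int, kind: str, cost: int,
                           dummy_len: int = 0) -> int:
        """Insert a dummy/breaking biarc as a twin pair of arc objects."""
        aid = len(self.arcs)
        rc_tail = self.nodes[head].twin
        rc_head = self.nodes[tail].twin
        self._register_arc(
            Arc(aid, tail, head, kind, cost, aid + 1, dummy_len=dummy_len)
        )
        self._register_arc(
            Arc(aid + 1, rc_tail, rc_head, kind, cost, aid, dummy_len=dummy_len)
        )
        return aid

    def add_dummy_biarc(self, tail: int, head: int, length: int) -> int:
        if not 1 <= length <= self.k - 1:
            raise GraphError(f"dummy length must be in [1, k-1], got {length}")
        return self._add_inserted_pair(tail, head, DUMMY, length, length)

    def add_breaking_biarc(self, tail: int, head: int) -> int:
        return self._add_inserted_pair(tail, head, BREAKING, self.k - 1)

    # -- queries ----------------------------------------------------------

    def arc_label(self, arc_id: int) -> str:
        arc = self.arcs[arc_id]
        if arc.kind != ORIGINAL:
            raise GraphError(f"arc {arc_id} ({arc.kind}) has no label")
        return self.store.get(arc.offset, arc.length, arc.forward)

    def out_arcs(self, node: int) -> list[int]:
        return self._out[node]

    def in_arcs(self, node: int) -> list[int]:
        return self._in[node]

    def original_out(self, node: int) -> list[int]:
        return [a for a in self._out[node] if self.arcs[a].kind == ORIGINAL]

    def original_in(self, node: int) -> list[int]:
        return [a for a in self._in[node] if self.arcs[a].kind == ORIGINAL]

    def iter_biarcs(self, kind: str | None = None) -> list[int]:
        """One representative arc id per biarc (the smaller of the twin pair)."""
        return [
            a.id
            for a in self.arcs
            if a.id <= a.twin and (kind is None or a.kind == kind)
        ]

    def binode_reps(self) -> list[int]:
        """One representative node id per binode (the smaller of the twin pair)."""
        return [n.id for n in self.nodes if n.id <= n.twin]

    def connected_components(self) -> list[list[int]]:
        """Connected components as sorted node-id lists, ordered by smallest id.

        Connectivity is over biarcs of any kind, ignoring direction, with twin
        nodes always in the same component.
        """
        parent = list(range(len(self.nodes)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

        for n in self.nodes:
            union(n.id, n.twin)
        for a in self.arcs:
            union(a.tail, a.head)
        groups: dict[int, list[int]] = {}
        for n in self.nodes:
            groups.setdefault(find(n.id), []).append(n.id)
        return [sorted(groups[r]) for r in sorted(groups)]


# -- unitig enumeration at the k-mer level --------------------------------


def _doubled_arcs(kmers: set[str]) -> list[str]:
    arcs: set[str] = set()
    for km in kmers:
        arcs.add(km)
        arcs.add(dna._rc_unchecked(km))
    return sorted(arcs)


def _maximal_unitig_strings(kmers: set[str], k: int) -> list[str]:
    """Maximal unitigs of a canonical k-mer set, as canonical strings.

    Works on the uncompacted doubled graph of k-mer arcs.  A unitig extension
    from arc f to arc e through node t requires t to have exactly one in- and
    one out-arc, e must not be the twin of f, and neither arc may be
    palindromic: palindromic k-mers stay singleton unitigs (they are
    self-complemental biarcs) and twin-adjacency would spell a string
    containing a k-mer twice.
    """
    km1 = k - 1
    arcs = _doubled_arcs(kmers)
    out_map: dict[str, list[str]] = {}
    in_map: dict[str, list[str]] = {}
    for a in arcs:
        out_map.setdefault(a[:km1], []).append(a)
        in_map.setdefault(a[-km1:], []).append(a)

    def palin(a: str) -> bool:
        return dna.is_self_complemental(a)

    def can_extend(f: str, e: str) -> bool:
        t = e[:km1]
        return (
            len(out_map.get(t, ())) == 1
            and len(in_map.get(t, ())) == 1
            and e != dna._rc_unchecked(f)
            and not palin(f)
            and not palin(e)
        )

    def is_start(e: str) -> bool:
        t = e[:km1]
        ins = in_map.get(t, ())
        if len(ins) != 1 or len(out_map.get(t, ())) != 1:
            return True
        return not can_extend(ins[0], e)

    used: set[str] = set()
    unitigs: list[str] = []

    def emit(seq: list[str]) -> None:
        s = seq[0] + "".join(a[-1] for a in seq[1:])
        for a in seq:
            used.add(a)
            used.add(dna._rc_unchecked(a))
        unitigs.append(min(s, dna._rc_unchecked(s)))

    for e in arcs:
        if e in used or not is_start(e):
            continue
        seq = [e]
        cur = e
        while True:
            outs = out_map.get(cur[-km1:], ())
            if len(outs) != 1:
                break
            nxt = outs[0]
            if not can_extend(cur, nxt) or nxt == e or nxt in used:
                break
            seq.append(nxt)
            cur = nxt
        emit(seq)

    # Leftover arcs form twin-disjoint simple cycles (every node 1-in/1-out,
    # no palindromes, no twin adjacency); open each at its smallest arc.
    for e in arcs:
        if e in used:
            continue
        seq = [e]
        cur = e
        while True:
            nxt = out_map[cur[-km1:]][0]
            if nxt == e:
                break
            seq.append(nxt)
            cur = nxt
        emit(seq)

    return sorted(set(unitigs))


def build_graph(
    strings: list[str], k: int, min_abundance: int = 1
) -> BidirectedDbg:
    """Build the compacted bidirected de Bruijn graph of a set of strings.

    ``min_abundance`` drops canonical k-mers occurring fewer than that many
    times in the input (a simple count threshold, default keep-all).
    """
    if k < 2:
        raise GraphError(f"k must be >= 2, got {k}")
    if min_abundance > 1:
        counts = dna.count_canonical_kmers(strings, k)
        for s in strings:
            dna.validate(s)
            if len(s) < k:
                raise dna.DnaError(f"string shorter than k={k}: {s!r}")
        kmers = {km for km, c in counts.items() if c >= min_abundance}
    else:
        kmers = dna.spectrum(strings, k)
    graph = BidirectedDbg(k)
    for unitig in _maximal_unitig_strings(kmers, k):
        graph.add_original_biarc(unitig)
    return graph


def maximal_unitigs(graph: BidirectedDbg) -> Spss:
    """The maximal-unitig SPSS: one string per original biarc."""
    return Spss(
        [graph.arc_label(a) for a in graph.iter_biarcs(ORIGINAL)], graph.k
    )


def spell(walk: Biwalk | list[int], graph: BidirectedDbg) -> str:
    """Spell the string of a biwalk.

    The first biarc contributes its full label (it must be an original arc);
    every further original biarc contributes its label minus the (k-1)-overlap;
    a dummy biarc of length l contributes the last l characters of its head
    node's (k-1)-mer, thereby re-spelling the k-mers along the path it stands
    for.  Breaking arcs never occur inside spelled walks.
    """
    arc_ids = list(walk.arcs if isinstance(walk, Biwalk) else walk)
    if not arc_ids:
        raise GraphError("cannot spell an empty walk")
    first = graph.arcs[arc_ids[0]]
    if first.kind != ORIGINAL:
        raise GraphError("a spelled walk must start with an original biarc")
    parts = [graph.arc_label(first.id)]
    prev = first
    for aid in arc_ids[1:]:
        arc = graph.arcs[aid]
        if arc.tail != prev.head:
            raise GraphError(
                f"walk not consecutive: arc {prev.id} head {prev.head} != "
                f"arc {arc.id} tail {arc.tail}"
            )
        if arc.kind == ORIGINAL:
            parts.append(graph.arc_label(aid)[graph.k - 1 :])
        elif arc.kind == DUMMY:
            parts.append(graph.nodes[arc.head].label[-arc.dummy_len :])
        else:
            raise GraphError("breaking arcs cannot be spelled")
        prev = arc
    return "".join(parts)
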