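"""Synthetic inputs and brute-force reference oracles.

The generators are pure functions of (seed, parameters) using the stdlib
Mersenne-Twister (``random.Random``), so fixtures reproduce across platforms.
The oracles are deliberately written against the raw k-mer set with their own
tiny unitig table — they share no code with the graph machinery they check.

``brute_force_min_spss`` performs exhaustive branch-and-bound over ordered
walk decompositions of the biarc set and returns the true minimum cumulative
length (with or without k-mer repetition) plus a witness string set.  Runs of
consecutive repeated arcs are capped at total cost k-1: a longer repeated
stretch can always be replaced by breaking the string there (cost k-1), so
the cap never excludes an optimal solution.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from . import dna


class SizeError(ValueError):
    """The instance is too large for exhaustive search."""


# -- generators --------------------------------------------------------------


def random_genome(seed: int, length: int) -> str:
    """Uniform i.i.d. DNA string of the given length, reproducible per seed."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = random.Random(seed)
    return "".join(rng.choice(dna.ALPHABET) for _ in range(length))


def random_pangenome(
    seed: int, base_length: int, n_copies: int, sub_rate: float
) -> list[str]:
    """A base genome plus mutated copies with i.i.d. substitutions.

    Returns ``n_copies`` strings: the base genome first, then copies where
    each position is substituted with probability ``sub_rate`` by one of the
    three other bases (chosen uniformly).
    """
    if not 0 <= sub_rate <= 1:
        raise ValueError(f"sub_rate must be in [0, 1], got {sub_rate}")
    rng = random.Random(seed)
    base = "".join(rng.choice(dna.ALPHABET) for _ in range(base_length))
    genomes = [base]
    for _ in range(n_copies - 1):
        chars = []
        for c in base:
            if rng.random() < sub_rate:
                chars.append(rng.choice([b for b in dna.ALPHABET if b != c]))
            else:
                chars.append(c)
        genomes.append("".join(chars))
    return genomes


def random_reads(
    seed: int, genome: str, n_reads: int, read_length: int
) -> list[str]:
    """Error-free reads drawn uniformly from both strands of a genome."""
    if read_length > len(genome):
        raise ValueError("read length exceeds genome length")
    rng = random.Random(seed)
    reads = []
    for _ in range(n_reads):
        start = rng.randrange(len(genome) - read_length + 1)
        read = genome[start : start + read_length]
        if rng.random() < 0.5:
            read = dna.reverse_complement(read)
        reads.append(read)
    return reads


# -- independent mini unitig table for the oracle ----------------------------


@dataclass(frozen=True)
class _OArc:
    seq: str  # oriented unitig string
    biarc: int  # index of its biarc (shared with the reverse orientation)
    cost: int


def _oracle_unitigs(kmers: set[str], k: int) -> list[str]:
    """Maximal unitigs of a canonical k-mer set, dict-based, for the oracle."""
    rc = dna._rc_unchecked
    arcs = sorted({o for km in kmers for o in (km, rc(km))})
    nxt: dict[str, list[str]] = {}
    prv: dict[str, list[str]] = {}
    for a in arcs:
        nxt.setdefault(a[: k - 1], []).append(a)
        prv.setdefault(a[1:], []).append(a)

    def joinable(f: str, e: str) -> bool:
        t = e[: k - 1]
        return (
            len(nxt.get(t, ())) == 1
            and len(prv.get(t, ())) == 1
            and e != rc(f)
            and f != rc(f)
            and e != rc(e)
        )

    done: set[str] = set()
    out: list[str] = []

    def take(chain: list[str]) -> None:
        s = chain[0] + "".join(a[-1] for a in chain[1:])
        done.update(chain)
        done.update(rc(a) for a in chain)
        out.append(min(s, rc(s)))

    for a in arcs:
        if a in done:
            continue
        ins = prv.get(a[: k - 1], ())
        if len(ins) == 1 and len(nxt.get(a[: k - 1], ())) == 1 and joinable(ins[0], a):
            continue  # not a chain start
        chain = [a]
        while True:
            outs = nxt.get(chain[-1][1:], ())
            if len(outs) != 1 or not joinable(chain[-1], outs[0]):
                break
            if outs[0] == a or outs[0] in done:
                break
            chain.append(outs[0])
        take(chain)
    for a in arcs:  # leftover simple cycles
        if a in done:
            continue
        chain = [a]
        while True:
            follow = nxt[chain[-1][1:]][0]
            if follow == a:
                break
            chain.append(follow)
        take(chain)

    # self-check: the table must cover each canonical k-mer exactly once
    seen: list[str] = []
    for s in out:
        for i in range(len(s) - k + 1):
            seen.append(dna.canonical(s[i : i + k]))
    if sorted(seen) != sorted(kmers):
        raise AssertionError("oracle unitig table does not tile the k-mer set")
    return sorted(out)


# -- brute-force minimum SPSS -------------------------------------------------


def brute_force_min_spss(
    kmers: set[str],
    k: int,
    allow_repeats: bool = True,
    upper_bound: int | None = None,
    max_kmers: int = 64,
) -> tuple[int, list[str]]:
    """True minimum CL of an SPSS of a canonical k-mer set, with a witness.

    Branch-and-bound over ordered walk decompositions of the biarc set:
    every walk starts a string (k-1 characters plus its arcs), extensions cost
    one character per uncompacted arc, and with ``allow_repeats`` a walk may
    re-traverse covered biarcs in stretches of total cost at most k-1.
    Walks are enumerated with non-decreasing first-arc index, which removes
    ordering symmetry without excluding any walk multiset.  Exponential:
    refuses instances above ``max_kmers`` canonical k-mers.
    """
    kmers = {dna.canonical(km) for km in kmers}
    if any(len(km) != k for km in kmers):
        raise ValueError("k-mer of wrong length in input set")
    if not kmers:
        raise ValueError("empty k-mer set")
    if len(kmers) > max_kmers:
        raise SizeError(
            f"{len(kmers)} canonical k-mers exceeds exhaustive-search limit "
            f"{max_kmers}"
        )
    rc = dna._rc_unchecked
    unitigs = _oracle_unitigs(kmers, k)

    # connected components of the bidirected graph: walks cannot leave one,
    # so the minimum CL is the sum of per-component minima
    comp_parent: dict[str, str] = {}

    def cfind(x: str) -> str:
        comp_parent.setdefault(x, x)
        while comp_parent[x] != x:
            comp_parent[x] = comp_parent[comp_parent[x]]
            x = comp_parent[x]
        return x

    def cunion(a: str, b: str) -> None:
        ra, rb = cfind(a), cfind(b)
        if ra != rb:
            comp_parent[rb] = ra

    for s in unitigs:
        t, h = s[: k - 1], s[-(k - 1):]
        cunion(t, rc(t))
        cunion(h, rc(h))
        cunion(t, h)
    groups: dict[str, list[str]] = {}
    for s in sorted(unitigs):
        groups.setdefault(cfind(s[: k - 1]), []).append(s)

    cl = 0
    witness: list[str] = []
    for root in sorted(groups):
        c_cl, c_wit = _min_spss_component(groups[root], k, allow_repeats)
        cl += c_cl
        witness.extend(c_wit)
    assert cl == sum(len(s) for s in witness)
    if upper_bound is not None and cl > upper_bound:
        raise AssertionError(
            f"oracle CL {cl} exceeds achievable upper bound {upper_bound}"
        )
    return cl, witness


def _min_spss_component(
    unitigs: list[str], k: int, allow_repeats: bool, max_states: int = 4_000_000
) -> tuple[int, list[str]]:
    """Exact min-CL walk decomposition of one connected biarc component.

    Best-first search (A*) over states (covered biarc set, walk head, repeat
    run).  The heuristic is admissible: every uncovered biarc still costs its
    own characters; if anything is uncovered at least one more string start
    (k-1) is needed unless the open walk can still reach it; and every unit of
    walk-degree imbalance of the uncovered arc set beyond what the free walk
    endpoints absorb costs at least one extra repeated character.  The first
    goal expansion is therefore optimal.
    """
    rc = dna._rc_unchecked
    n = len(unitigs)
    oarcs: list[_OArc] = []
    for i, s in enumerate(unitigs):
        oarcs.append(_OArc(s, i, len(s) - k + 1))
        if rc(s) != s:
            oarcs.append(_OArc(rc(s), i, len(s) - k + 1))
    oarcs.sort(key=lambda a: a.seq)
    by_tail: dict[str, list[int]] = {}
    for idx, a in enumerate(oarcs):
        by_tail.setdefault(a.seq[: k - 1], []).append(idx)
    cost_of = [len(s) - k + 1 for s in unitigs]
    total_cost = sum(cost_of)
    full = (1 << n) - 1
    run_cap = k - 1

    # walk-degree imbalance of the uncovered arc set, per binode orientation:
    # delta[rep] = (uncovered out at rep) - (uncovered in at rep); |delta|
    # summed over binode representatives, halved, bounds the endpoints+repeats
    # needed.  Self-complemental endpoints are skipped (conservative).
    node_rep: dict[str, tuple[str, int]] = {}
    for a in oarcs:
        for km1 in (a.seq[: k - 1], a.seq[-(k - 1):]):
            r = rc(km1)
            node_rep[km1] = (min(km1, r), 1 if km1 <= r else -1)
    arc_delta: list[list[tuple[str, int]]] = []  # per biarc: (rep, +-1) effects
    for i, s in enumerate(unitigs):
        effects: list[tuple[str, int]] = []
        t, h = s[: k - 1], s[-(k - 1):]
        for km1, sign in ((t, 1), (h, -1)):
            rep, orient = node_rep[km1]
            if rep != rc(rep):  # skip self-complemental binodes
                effects.append((rep, sign * orient))
        arc_delta.append(effects)

    import heapq

    # static capped all-pairs min-cost distances between oriented (k-1)-mers;
    # repeat stretches can only use arcs of the graph, so these underestimate
    # any future repeat cost
    dist: dict[str, dict[str, int]] = {}
    for src in {a.seq[: k - 1] for a in oarcs} | {a.seq[-(k - 1):] for a in oarcs}:
        d_map = {src: 0}
        frontier = [(0, src)]
        while frontier:
            c, node = heapq.heappop(frontier)
            if c > d_map.get(node, c):
                continue
            for idx in by_tail.get(node, ()):
                a = oarcs[idx]
                nc = c + a.cost
                tgt = a.seq[-(k - 1):]
                if nc <= k - 1 and nc < d_map.get(tgt, nc + 1):
                    d_map[tgt] = nc
                    heapq.heappush(frontier, (nc, tgt))
        dist[src] = d_map

    h_cache: dict[tuple, int] = {}

    def heuristic(mask: int, head: str | None,
                  remaining: int, delta: dict[str, int]) -> int:
        """Admissible completion bound.

        Each unit of uncovered-set imbalance must be absorbed by a walk
        endpoint (two per walk of cost k-1, i.e. at least (k-1)/2 per unit)
        or by a repeat stretch connecting it to another unit (at least the
        capped min-cost path, charged half to each end).  An open walk gets
        its two cheapest absorptions for free.  Balanced-but-uncovered
        leftovers still need one more string start when no walk is open.
        """
        if mask == full:
            return 0
        key = (tuple(sorted(delta.items())), head is not None)
        cached = h_cache.get(key)
        if cached is not None:
            return remaining + cached
        units: list[tuple[str, str]] = []  # (tail attachment, head attachment)
        for rep, v in delta.items():
            if v == 0:
                continue
            tail, headn = (rc(rep), rep) if v > 0 else (rep, rc(rep))
            units.extend([(tail, headn)] * abs(v))
        charges = []
        for i, (ta, ha) in enumerate(units):
            best = k - 1
            if allow_repeats:
                for j, (tb, hb) in enumerate(units):
                    if i == j:
                        continue
                    ab = dist.get(ta, {}).get(hb)
                    ba = dist.get(tb, {}).get(ha)
                    for c in (ab, ba):
                        if c is not None and 0 < c < best:
                            best = c
            charges.append(best)
        if head is not None:
            # the open walk's entry and final end absorb two units for free;
            # assume adversarially they absorb the most expensive ones
            charges.sort()
            charges = charges[:-2] if len(charges) > 2 else []
            start = 0
        else:
            start = (k - 1) if not charges else 0
        pair_bound = sum(charges) // 2
        core = max(start, pair_bound)
        h_cache[key] = core
        return remaining + core

    start_state = (0, None, 0)
    g_best: dict[tuple, int] = {start_state: 0}
    parents: dict[tuple, tuple] = {}
    delta0: dict[str, int] = {}
    for i in range(n):
        for rep, eff in arc_delta[i]:
            delta0[rep] = delta0.get(rep, 0) + eff
    # states carry (mask, head, run); remaining/delta ride along heap entries
    counter = 0
    heap: list = []

    def push(state, g, remaining, delta_items, parent, action):
        nonlocal counter
        h = heuristic(state[0], state[1], remaining, dict(delta_items))
        counter += 1
        heapq.heappush(heap, (g + h, g, counter, state, remaining, delta_items))
        if parent is not None:
            parents[state] = (parent, action)

    push(start_state, 0, total_cost, tuple(sorted(delta0.items())), None, None)
    expansions = 0
    goal: tuple | None = None
    while heap:
        f, g, _, state, remaining, delta_items = heapq.heappop(heap)
        if g > g_best.get(state, g):
            continue
        mask, head, run = state
        if mask == full and head is None:
            goal = state
            break
        expansions += 1
        if expansions > max_states:
            raise SizeError(
                f"component search exceeded {max_states} state expansions"
            )
        delta = dict(delta_items)

        def consider(nstate, ng, nremaining, ndelta, action):
            prev = g_best.get(nstate)
            if prev is None or ng < prev:
                g_best[nstate] = ng
                push(nstate, ng, nremaining,
                     tuple(sorted(ndelta.items())), state, action)

        if head is None:
            for idx, a in enumerate(oarcs):
                bit = 1 << a.biarc
                if mask & bit:
                    continue
                # covering removes the biarc's contribution to the
                # uncovered-set imbalance
                nd = dict(delta)
                for rep, eff in arc_delta[a.biarc]:
                    nd[rep] = nd.get(rep, 0) - eff
                consider((mask | bit, a.seq[-(k - 1):], 0),
                         g + (k - 1) + a.cost,
                         remaining - a.cost, nd, ("start", idx))
        else:
            consider((mask, None, 0), g, remaining, delta, ("close",))
            for idx in by_tail.get(head, ()):
                a = oarcs[idx]
                bit = 1 << a.biarc
                if not mask & bit:
                    nd = dict(delta)
                    for rep, eff in arc_delta[a.biarc]:
                        nd[rep] = nd.get(rep, 0) - eff
                    consider((mask | bit, a.seq[-(k - 1):], 0),
                             g + a.cost, remaining - a.cost, nd,
                             ("extend", idx))
                elif allow_repeats and run + a.cost <= run_cap:
                    consider((mask, a.seq[-(k - 1):], run + a.cost),
                             g + a.cost, remaining, delta, ("repeat", idx))

    if goal is None:
        raise AssertionError("search exhausted without covering all biarcs")

    # rebuild the witness strings from the action trail
    actions: list[tuple] = []
    state = goal
    while state in parents:
        state, action = parents[state]
        actions.append(action)
    actions.reverse()
    strings: list[str] = []
    current: str | None = None
    for action in actions:
        if action[0] == "close":
            if current is not None:
                strings.append(current)
                current = None
        elif action[0] == "start":
            if current is not None:
                strings.append(current)
            current = oarcs[action[1]].seq
        else:
            current += oarcs[action[1]].seq[k - 1 :]
    if current is not None:
        strings.append(current)
    cl = sum(len(s) for s in strings)
    assert cl == g_best[goal]
    return cl, strings


def exhaustive_kmer_min_spss(kmers: set[str], k: int, max_kmers: int = 8) -> int:
    """Second, even more literal oracle: walk decompositions at k-mer level.

    Used in the test suite to validate the arc-level oracle on tiny sets.
    """
    kmers = {dna.canonical(km) for km in kmers}
    if len(kmers) > max_kmers:
        raise SizeError("too many k-mers for the k-mer-level oracle")
    rc = dna._rc_unchecked
    doubled = sorted({o for km in kmers for o in (km, rc(km))})
    index = {km: i for i, km in enumerate(sorted(kmers))}
    full = (1 << len(kmers)) - 1
    best = [len(kmers) * k]

    def dfs(head: str | None, mask: int, run: int, cost: int) -> None:
        if cost + (full ^ mask).bit_count() >= best[0]:
            return
        if mask == full:
            best[0] = cost
            return
        if head is not None:
            for c in dna.ALPHABET:
                km = head + c
                canon = dna.canonical(km)
                if canon not in index:
                    continue
                bit = 1 << index[canon]
                if not mask & bit:
                    dfs(km[1:], mask | bit, 0, cost + 1)
                elif run < k - 1:
                    dfs(km[1:], mask, run + 1, cost + 1)
        for km in doubled:
            bit = 1 << index[dna.canonical(km)]
            if not mask & bit:
                dfs(km[1:], mask | bit, 0, cost + k)

    dfs(None, 0, 0, 0)
    return best[0]


# -- brute-force matching oracle ----------------------------------------------


def brute_force_matching(instance) -> int:
    """Minimum cost over all perfect matchings, by exhaustive enumeration.

    *instance* is an undirected graph (networkx-compatible: ``.nodes``,
    ``.edges[u, v]['weight']``, ``.neighbors``) with at most ~10 nodes.
    """
    nodes = sorted(instance.nodes, key=repr)
    if len(nodes) > 16:
        raise SizeError("too many nodes for exhaustive matching")
    if len(nodes) % 2 != 0:
        raise ValueError("perfect matching needs an even number of nodes")

    best: list[int | None] = [None]

    def rec(unmatched: list, cost: int) -> None:
        if best[0] is not None and cost >= best[0]:
            return
        if not unmatched:
            best[0] = cost
            return
        first = unmatched[0]
        rest = unmatched[1:]
        for other in rest:
            if instance.has_edge(first, other):
                rec(
                    [x for x in rest if x != other],
                    cost + instance.edges[first, other]["weight"],
                )

    rec(nodes, 0)
    if best[0] is None:
        raise ValueError("no perfect matching exists")
    return best[0]
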