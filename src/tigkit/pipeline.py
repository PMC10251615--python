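"""End-to-end tig computation, SPSS validation, metrics and membership query.

``compute_tigs`` is the facade over the whole machinery:

1. build the compacted bidirected de Bruijn graph of the input,
2. classify bi-imbalances,
3. (matchtigs) capped many-to-many min-cost paths between unbalanced
   orientations, min-cost matching with unmatched penalties, interpreted as
   joining/breaking arcs — or (greedy) nearest-sink joins — or (eulertigs)
   breaking arcs only,
4. Eulerise, compute a biEulerian circuit per component, break it, and spell
   the walks.

Matchtigs output has minimum cumulative length CL among all SPSSs of the
input; Eulertigs are the CL-minimum among SPSSs without k-mer repetition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from . import dna
from .balance import classify, many_to_many_paths
from .eulertour import bi_eulerian_circuit, break_circuit, eulerise, greedy_plan
from .graph import (
    DUMMY,
    ORIGINAL,
    BidirectedDbg,
    build_graph,
    maximal_unitigs,
    spell,
)
from .matching import (
    EulerisationPlan,
    build_matching_graph,
    eulertigs_plan,
    interpret_matching,
    reduce_to_perfect,
    solve_perfect_matching,
)
from .spss import Metrics, Spss, metrics

logger = logging.getLogger(__name__)

ALGORITHMS = ("unitigs", "eulertigs", "greedy", "matchtigs")


class PipelineError(ValueError):
    pass


def _input_fragments(records, k: int) -> list[str]:
    """Clean raw sequences and keep fragments long enough to hold a k-mer."""
    fragments: list[str] = []
    for rec in records:
        seq = rec.seq if hasattr(rec, "seq") else rec
        fragments.extend(f for f in dna.clean_fragments(str(seq)) if len(f) >= k)
    return fragments


def _matchtigs_plan(graph: BidirectedDbg, threads: int = 1) -> EulerisationPlan:
    table = classify(graph)
    if table.is_bi_eulerian:
        logger.info("graph is biEulerian; matching step skipped")
        return EulerisationPlan()
    paths = many_to_many_paths(graph, table, threads=threads)
    logger.info(
        "demands: %d binodes (%d units), path table: %d entries",
        len(table.demands),
        sum(d.units for d in table.demands.values()),
        len(paths),
    )
    m = build_matching_graph(table, paths, graph.k)
    instance = reduce_to_perfect(m, graph.k)
    solution = solve_perfect_matching(instance)
    return interpret_matching(solution, table, paths, graph.k)


def _spell_all(graph: BidirectedDbg) -> Spss:
    """Circuit + break + spell per connected component, in node-id order."""
    strings: list[str] = []
    k = graph.k
    for comp in graph.connected_components():
        if not any(graph.out_arcs(v) for v in comp):
            continue
        circuit = bi_eulerian_circuit(graph, comp)
        for walk in break_circuit(circuit, graph):
            s = spell(walk, graph)
            walk_cost = sum(graph.arcs[a].cost for a in walk.arcs)
            # walk-size identity: one character per uncompacted arc
            assert len(s) == (k - 1) + walk_cost, (
                f"spell length {len(s)} != (k-1) + walk cost {walk_cost}"
            )
            strings.append(s)
    return Spss(strings, k)


def compute_tigs(
    records,
    k: int,
    algo: str = "matchtigs",
    min_abundance: int = 1,
    threads: int = 1,
) -> Spss:
    """Compute an SPSS of the input records with the requested algorithm.

    *records* may be SeqRecord-like objects or plain strings; non-ACGT runs
    are split out before k-mer extraction.  ``min_abundance`` drops canonical
    k-mers seen fewer than that many times.
    """
    if algo not in ALGORITHMS:
        raise PipelineError(f"unknown algorithm {algo!r}; use one of {ALGORITHMS}")
    fragments = _input_fragments(records, k)
    if not fragments:
        raise PipelineError(f"input contains no k-mers at k={k}")
    graph = build_graph(fragments, k, min_abundance=min_abundance)
    if not graph.arcs:
        raise PipelineError("empty k-mer spectrum after filtering")
    logger.info(
        "graph: %d binodes, %d biarcs (k=%d, algo=%s)",
        len(graph.binode_reps()),
        len(graph.iter_biarcs(ORIGINAL)),
        k,
        algo,
    )
    if algo == "unitigs":
        return maximal_unitigs(graph)
    if algo == "eulertigs":
        plan = eulertigs_plan(classify(graph))
    elif algo == "greedy":
        plan = greedy_plan(graph)
    else:
        plan = _matchtigs_plan(graph, threads=threads)
    logger.info(
        "plan: %d joining, %d breaking biarcs", len(plan.joining), len(plan.breaking)
    )
    eulerise(graph, plan)
    return _spell_all(graph)


@dataclass
class ValidationReport:
    """Two-way spectrum comparison between an input and an SPSS."""

    ok: bool
    missing: list[str] = field(default_factory=list)  # in input, not in SPSS
    extra: list[str] = field(default_factory=list)  # in SPSS, not in input

    def __bool__(self) -> bool:
        return self.ok


def validate_spss(records, spss: Spss) -> ValidationReport:
    """Check spec_k(SPSS) == spec_k(input); report differences."""
    fragments = _input_fragments(records, spss.k)
    want = dna.spectrum(fragments, spss.k) if fragments else set()
    got = spss.spectrum()
    missing = sorted(want - got)
    extra = sorted(got - want)
    return ValidationReport(not missing and not extra, missing, extra)


@dataclass
class QueryResult:
    read_id: str
    hits: int
    total: int
    present: bool
    skipped: bool = False


def query(spss: Spss, reads, theta: float = 0.8) -> list[QueryResult]:
    """Threshold membership query against the k-mer set of an SPSS.

    A read Q is present iff at least floor(theta * (|Q|-k+1)) of its k-mers
    (canonically) are in the spectrum — boundary inclusive — and it has at
    least one hit.  Reads shorter than k are flagged and excluded.
    """
    if not 0 < theta <= 1:
        raise PipelineError(f"theta must be in (0, 1], got {theta}")
    k = spss.k
    spectrum = spss.spectrum()
    results = []
    for i, rec in enumerate(reads):
        rid = getattr(rec, "id", None) or f"read_{i}"
        seq = str(rec.seq if hasattr(rec, "seq") else rec).upper()
        if len(seq) < k:
            results.append(QueryResult(rid, 0, 0, False, skipped=True))
            continue
        total = len(seq) - k + 1
        hits = sum(
            1
            for km in dna.iter_kmers(seq, k)
            if set(km) <= set(dna.ALPHABET) and dna.canonical(km) in spectrum
        )
        # guard against float floor undershoot on exact products (e.g. 0.7*10)
        threshold = max(1, math.floor(theta * total + 1e-9))
        results.append(QueryResult(rid, hits, total, hits >= threshold))
    return results
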