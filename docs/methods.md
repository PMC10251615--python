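# Methods

## Model

tigkit represents a DNA k-mer set as a compacted bidirected arc-centric de
Bruijn graph stored as a *doubled* directed graph: every (k−1)-mer node and
every unitig arc exists in both orientations, with an explicit twin pairing.
A node or arc equal to its own reverse complement is its own twin
(*self-complemental*); for DNA alphabets a self-complemental node requires an
even label length (so odd k) and a self-complemental arc an even label length
(so even k) — the two cases are mutually exclusive. Arc cost is
|label| − (k−1), the number of k-mers the unitig carries, so walk cost counts
one character per uncompacted arc and the size of a string set spelled by
walks W is exactly |W|·(k−1) + Σ|w|.

A minimum SPSS is a minimum-cost set of biwalks covering every original
biarc. tigkit reduces this to a bidirected partial-coverage Chinese postman
problem: augment the graph with breaking arcs of cost k−1 (a breaking arc in
the final circular walk marks a cut between two output strings) and find a
min-cost circular biwalk covering all original biarcs and at least one
breaking biarc. The Eulerisation view makes this tractable: choose a
multiset of inserted arcs that makes every binode balanced and every
self-complemental node even, then any biEulerian circuit of the augmented
graph, broken at the breaking arcs, spells an optimal string set.

### Bi-imbalance

For a binode [v, v⁻¹] with v ≠ v⁻¹, restricted to the original arc set F:

    bi_v = d_F⁺(v) − d_F⁻(v) + 1[(v,v⁻¹) ∈ F⁺(v)] − 1[(v⁻¹,v) ∈ F⁻(v)]

The indicator terms implement the fact that a self-complemental biarc incident
to the binode consumes two slots of the same direction. For a
self-complemental binode [v] only parity matters: bi_v = d_F⁺(v) mod 2.
A binode with bi_v < 0 at orientation v is missing outgoing cover at v;
its twin orientation is missing incoming cover. Inserted biarcs are oriented
from a negative orientation to a positive one.

### Matching

Each unbalanced binode contributes |bi_v| copies to an undirected matching
graph (odd-parity self-complemental binodes one copy). Capped Dijkstra
searches (priority ties broken by node id; sparse distance maps; frontier
abandoned past cost k−1) from every negative orientation yield min-cost
connections to all positive orientations; one edge per unordered binode pair
is kept, at the cheaper of the two orientations. Matching an edge inserts a
joining (dummy) arc whose length equals the path cost; an unmatched copy
costs (k−1)/2 because every *pair* of unmatched copies is later fixed by one
breaking arc. A forcing pair {u, w} with zero-cost edges to every copy and no
u–w edge guarantees at least two unmatched copies, hence a breakable circuit.
The penalised problem reduces to min-cost perfect matching by duplicating the
graph with cost-(k−1) node–copy edges (u, w excluded); all costs stay
integral. The exact blossom solver in networkx computes the optimum, and the
original half of the doubled solution is interpreted (both halves are
minimum). Unmatched copies are paired by sorted binode id — every pairing
has equal cost — and oriented negative-to-positive, which covers the
same-binode case (a self-complemental breaking connection) uniformly.

The cap k−1 is used rather than the k−2 that already suffices for
length-optimality, because joins of cost exactly k−1 are length-neutral but
reduce the string count.

### Inserted arcs as twin pairs

Dummy and breaking biarcs are always inserted as a pair of twin arc objects,
even when tail = twin(head) and the biarc would classically be a single
self-complemental arc. A parallel pair has identical balance, coverage and
spelling semantics (the circuit consumes both arcs in one traversal and the
walk spells the insertion once), and it keeps the post-Eulerisation balance
check free of special cases for inserted arcs. Original palindromic-k-mer
arcs remain genuine single self-complemental arcs; unitig compaction never
extends through them, nor through a twin-adjacent junction, so no unitig ever
spells a k-mer twice.

### Circuit and breaking

Circuits are computed per connected component (components ordered by smallest
node id) with Hierholzer-style edge consumption on the doubled graph:
traversing an arc consumes its twin, and the next arc out of a node is the
unused one with the smallest id, making circuits fully deterministic. The
circuit is broken at all breaking biarcs (they are discarded; one output walk
per breaking biarc). A circuit with dummies but no breaking arcs — possible
on the greedy route when all demands were joined — is broken at one longest
dummy (first on ties; only string count, not length, depends on the tie), and
a pure original cycle is opened at the smallest arc id. A biEulerian input
receives one breaking loop pair at the smallest node of each component, so
the output is always a set of linear strings. Walks always begin and end
with original arcs, because inserted arcs leave only negative orientations
and enter only positive ones.

Spelling: the first biarc contributes its label, later original biarcs their
label minus the (k−1) overlap, and a dummy of length ℓ the last ℓ characters
of its head node's (k−1)-mer — precisely the characters of the min-cost path
it stands for, which re-spells (repeats) the k-mers along that path. The
identity ‖S‖ = SC·(k−1) + Σ walk-arc-costs is asserted on every run.

### Greedy heuristic

The greedy route processes unbalanced binodes in id order; for each it runs
one capped search and commits joins to the nearest available partners
(ties by binode id) until its demand is met, including cost-(k−1) joins,
which never increase length but reduce string count. Leftover demand becomes
breaking arcs. Commits update the demand of both endpoints, so concurrent
schedules must serialise per-binode updates in ascending id order; the
single-worker in-order execution is the reference, and path searches may run
on several workers because the merged table is sorted before use — outputs
are a pure function of the graph, never of scheduling. The search block size
(default 64 sources) is purely a work-partitioning knob.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | required, ≥ 2 | k-mer length; 31 is typical for bacterial data |
| algo | matchtigs | unitigs / eulertigs / greedy / matchtigs |
| min_abundance | 1 | drop canonical k-mers seen fewer times (simple count filter) |
| theta | 0.8 | membership-query inclusion rate |
| threads | 1 | workers for path searches; results identical for any value |

The membership query declares a read present when at least
⌊θ·(|Q|−k+1)⌋ of its k-mers are in the set, boundary inclusive, with the
natural proviso that a read with zero hits is never present (the literal
floor rule would otherwise admit any read once ⌊θ·n⌋ = 0). Reads shorter
than k are flagged and excluded.

Non-ACGT input (N, IUPAC codes, lowercase) is uppercased and split at every
non-ACGT run before k-mer extraction, mirroring standard unitig builders.

## Synthetic data

The generators are pure functions of (seed, parameters) over the stdlib
Mersenne-Twister. `random_genome` draws uniform i.i.d. bases — a maximally
tangled graph at small k, which is the stress case for balance bookkeeping
but lacks the long repeats of real genomes. `random_pangenome` emulates a
bacterial pangenome as n mutated copies of one base genome with i.i.d.
substitutions (no indels, no rearrangements); it produces the bubble-rich
graphs where joining pays off, but real pangenomes additionally contain
structural variation and mobile elements. `random_reads` draws error-free
fixed-length reads from both strands. Tests passing on these inputs
demonstrate correctness of the combinatorics — spectrum preservation,
optimality, determinism — on every graph shape the generators reach,
including palindromic and self-complemental cases; they do not measure the
compression ratios or performance a tool would achieve on real data.

## Oracles

`brute_force_min_spss` finds the true minimum SPSS size by exhaustive search,
independently of the graph machinery: it tiles the k-mer set with its own
dict-based unitig table (self-checked to cover each canonical k-mer exactly
once), splits into connected components, and runs an exact best-first search
over (covered set, walk head, repeat run) states. Runs of consecutive
repeated arcs are capped at total cost k−1 — a longer repeated stretch can
always be replaced by cutting the string there at cost k−1, so the cap never
excludes an optimum. The admissible completion bound charges every uncovered
arc its own characters, every unit of uncovered-set imbalance at least half
of min(k−1, cheapest connecting path), and one string start when nothing is
open; the first goal expansion is therefore optimal. Components above four
million state expansions are refused rather than approximated (not observed
at the study sizes; the guard exists for pathological inputs). A second,
purely k-mer-level exhaustive search cross-validates the oracle on tiny sets,
and every witness is verified to spell exactly the claimed spectrum at the
claimed size. `brute_force_matching` enumerates all perfect matchings of an
instance (≤ ~10 nodes) as the solver oracle.

Study sizes used by the test suite and the acceptance script: 100 random
genomes of length 20 and 50 pangenomes (base 20, 3 copies, substitution rate
0.1) at k = 5 for oracle equivalence; 200 inputs across k ∈ {5, 7, 11, 15}
for spectrum preservation; a 5 kb × 4-copy pangenome at k = 31 (8600
canonical k-mers) as the end-to-end demonstration. The base length of the
oracle pangenomes matches the genome condition; the demo size was chosen as
the smallest graph that exhibits pangenome-like tangledness with hundreds of
unitigs.

## Numerical and degenerate-input choices

All costs are integers throughout (the only conceptually fractional quantity,
the (k−1)/2 unmatched penalty, appears only pre-doubled inside the perfect
matching reduction). Deterministic tie-breaks: Dijkstra by (cost, node id);
greedy sinks by (cost, binode id); unmatched pairing by binode id; circuit
next-arc by arc id; components by smallest node id; output strings in
walk-discovery order. Equal-cost matchings may differ between solver
versions; only their cost is contractual. Degenerate inputs: empty spectra
and k < 2 are errors; single-k-mer inputs, palindromic k-mers, self-loops and
circular unitigs are regular cases with tests; duplicate input records are
harmless (the spectrum is a set).

## Limitations

Pure-Python scale: suitable for graphs up to roughly 10⁵ unitigs; the
matching instance grows with the square of the demand count, as in any exact
matchtig computation. The min-abundance filter is a plain count threshold,
an approximation of the streaming filters of production k-mer counters.
No minimiser/membership index is built — the query scans the spectrum set.
The string-count-minimal SPSS variant (covering via strongly connected
component condensation) is out of scope.
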