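# tigkit

Minimum plain-text representations of k-mer sets.

Many k-mer-based tools (membership queries, genotyping, metagenomic
classification, alignment-free comparison) only need the *set* of k-mers of a
sequence collection, not the de Bruijn graph topology that maximal unitigs
preserve. A **spectrum preserving string set** (SPSS) of an input *I* is any
set *S* of strings of length ≥ k with spec_k(S) = spec_k(I), where spec_k is
the set of k-mers read forward or reverse-complemented. Dropping the
no-repetition constraint of unitigs/simplitigs allows strictly smaller
representations: repeating up to k−2 characters to join two strings saves the
k−1 characters a new string would cost.

tigkit computes four representations of the same spectrum:

* **unitigs** — maximal non-branching paths; the baseline.
* **Eulertigs** — the minimum-cumulative-length SPSS *without* k-mer
  repetition, via breaking-arc Eulerisation of the bidirected de Bruijn graph.
* **greedy matchtigs** — a fast heuristic that joins each unbalanced node to
  its nearest reachable partner whenever the join does not increase size.
* **matchtigs** — the provably minimum-CL SPSS with repetition allowed.

## The algorithm

The input is compacted into a bidirected arc-centric de Bruijn graph: nodes
are (k−1)-mers paired with their reverse complements (*binodes*), arcs are
maximal unitigs paired with their reverse complements (*biarcs*) with cost
|label| − (k−1). An SPSS corresponds to a set of biwalks covering every
original biarc, and its size obeys

    ‖S‖ = |W|·(k−1) + Σ_{w∈W} |w|,

one character per uncompacted arc plus k−1 per string. Minimising ‖S‖ is a
bidirected partial-coverage Chinese postman problem: find a min-cost circular
biwalk covering all original biarcs, where artificial *breaking arcs* of cost
k−1 model starting a new string. tigkit solves it exactly by

1. computing the **bi-imbalance** bi_v of every binode (for self-complemental
   nodes only the parity of the degree matters),
2. running capped Dijkstra searches (cost ≤ k−1) from the negative
   orientation of every unbalanced binode to all positive orientations,
3. building a **min-cost matching** over |bi_v| copies of each unbalanced
   binode — path edges cost the connection, staying unmatched costs (k−1)/2,
   and a forcing pair {u, w} guarantees at least one breaking arc — reduced
   to min-cost perfect matching and solved with an exact blossom matcher,
4. Eulerising the graph with the chosen joining (dummy) and breaking arcs,
   extracting a biEulerian circuit per component, breaking it at all breaking
   arcs, and spelling the walks.

The output of the matching route is a minimum SPSS; the greedy route replaces
step 3 by nearest-sink joins and is near-optimal in practice while
additionally minimising string count on ties.

## Worked example

```sh
tigkit synth --seed 1 --length 5000 --copies 4 --sub-rate 0.01 -o pangenome.fa
for algo in unitigs eulertigs greedy matchtigs; do
    tigkit compute --algo $algo -k 31 -i pangenome.fa -o $algo.fa
done
```

prints (CL = total characters, SC = number of strings):

```
algo=unitigs	k=31	CL=19000	SC=331	duplicates=0
algo=eulertigs	k=31	CL=12370	SC=110	duplicates=0
algo=greedy	k=31	CL=11455	SC=55	duplicates=735
algo=matchtigs	k=31	CL=11359	SC=56	duplicates=609
```

The synthetic pangenome (four mutated copies of a 5 kb genome) has 8600
distinct canonical 31-mers. Unitigs need 19 000 characters in 331 strings;
Eulertigs remove the per-string overhead that joining without repetition can
save; the matchtig variants additionally repeat 609/735 k-mer occurrences to
cut the total to about 0.60× the unitig size in a sixth of the strings.
`tigkit validate` confirms every output spells exactly the input spectrum,
`tigkit stats` reports the metrics of an existing FASTA, and `tigkit query`
answers threshold membership queries (a read is present when at least
⌊θ·(|Q|−k+1)⌋ of its k-mers, and at least one, are in the set).

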