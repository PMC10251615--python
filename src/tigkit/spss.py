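"""Spectrum-preserving string sets and their size metrics.

An SPSS of an input string set I is a set of strings S (each of length >= k)
with spec_k(S) = spec_k(I); k-mers may repeat, both within and across strings.
The two quantities optimised/reported throughout the package are the
cumulative length CL = sum(|s|) and the string count SC = |S|.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from . import dna


@dataclass
class Spss:
    """An SPSS: output strings plus the k they were built for."""

    strings: list[str]
    k: int

    def __post_init__(self) -> None:
        for s in self.strings:
            if len(s) < self.k:
                raise dna.DnaError(
                    f"SPSS string shorter than k={self.k}: {s!r}"
                )

    def spectrum(self) -> set[str]:
        return dna.spectrum(self.strings, self.k)


@dataclass
class Metrics:
    """CL / SC / duplicate-k-mer metrics of an SPSS."""

    cl: int
    sc: int
    duplicate_kmers: int


def metrics(spss: Spss) -> Metrics:
    """Compute CL, SC and the number of duplicate k-mer occurrences.

    ``duplicate_kmers`` counts every occurrence beyond the first of each
    canonical k-mer across the whole string set; it is 0 for unitigs and
    Eulertigs by construction.
    """
    counts: Counter[str] = Counter()
    for s in spss.strings:
        for km in dna.iter_kmers(s, spss.k):
            counts[dna.canonical(km)] += 1
    dup = sum(c - 1 for c in counts.values())
    return Metrics(
        cl=sum(len(s) for s in spss.strings),
        sc=len(spss.strings),
        duplicate_kmers=dup,
    )


def duplicate_bitvectors(spss: Spss) -> list[str]:
    """Per-string ASCII bitvectors marking duplicate k-mer positions.

    For each output string there is one '0'/'1' character per k-mer position;
    '1' marks a k-mer whose canonical form already occurred earlier in the
    output (earlier string, or earlier position of the same string).
    """
    seen: set[str] = set()
    vectors: list[str] = []
    for s in spss.strings:
        bits = []
        for km in dna.iter_kmers(s, spss.k):
            c = dna.canonical(km)
            bits.append("1" if c in seen else "0")
            seen.add(c)
        vectors.append("".join(bits))
    return vectors
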