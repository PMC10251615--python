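"""DNA string primitives: validation, reverse complements and k-mer spectra.

All strings handled by the graph machinery are plain Python ``str`` over the
alphabet ``{A, C, G, T}``.  Input records may contain other characters
(``N``, IUPAC codes, lowercase); :func:`clean_fragments` uppercases and splits
them into valid fragments before any k-mer is extracted, mirroring what
standard unitig builders do.
"""

from __future__ import annotations

import re
from typing import Iterable

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_RE = re.compile(r"^[ACGT]+$")
_FRAGMENT_RE = re.compile(r"[ACGT]+")


class DnaError(ValueError):
    """Raised for invalid DNA input (bad alphabet, too-short strings, ...)."""


def validate(s: str) -> str:
    """Return *s* if it is a non-empty string over {A,C,G,T}, else raise."""
    if not s or not _VALID_RE.match(s):
        raise DnaError(f"not a valid DNA string: {s[:50]!r}")
    return s


def reverse_complement(s: str) -> str:
    """Reverse complement of *s* (an involution)."""
    validate(s)
    return s.translate(_COMPLEMENT)[::-1]


def _rc_unchecked(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """The lexicographically smaller of *kmer* and its reverse complement."""
    rc = _rc_unchecked(kmer)
    return kmer if kmer <= rc else rc


def is_self_complemental(s: str) -> bool:
    """True if *s* equals its own reverse complement (even length only, for DNA)."""
    return s == _rc_unchecked(s)


def clean_fragments(seq: str) -> list[str]:
    """Uppercase *seq* and split it at every non-ACGT run.

    Returns the list of maximal ACGT fragments, in order.  Fragments shorter
    than any later k threshold are filtered by the caller.
    """
    return _FRAGMENT_RE.findall(seq.upper())


def iter_kmers(s: str, k: int) -> Iterable[str]:
    for i in range(len(s) - k + 1):
        yield s[i : i + k]


def spectrum(strings: Iterable[str], k: int) -> set[str]:
    """Canonical k-mer spectrum of a collection of DNA strings.

    Every k-mer occurring forward or reverse-complemented in any string is
    included, represented by its canonical form.  Strings shorter than k are
    a validation error (the caller splits/filters fragments first).
    """
    if k < 2:
        raise DnaError(f"k must be >= 2, got {k}")
    out: set[str] = set()
    for s in strings:
        validate(s)
        if len(s) < k:
            raise DnaError(f"string shorter than k={k}: {s!r}")
        for km in iter_kmers(s, k):
            out.add(canonical(km))
    return out


def count_canonical_kmers(strings: Iterable[str], k: int) -> dict[str, int]:
    """Occurrence counts of canonical k-mers (one count per occurrence)."""
    counts: dict[str, int] = {}
    for s in strings:
        for km in iter_kmers(s, k):
            c = canonical(km)
            counts[c] = counts.get(c, 0) + 1
    return counts
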