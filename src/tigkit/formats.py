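"""Readers and writers: FASTA (plain or gzip), GFA1, duplicate bitvectors.

FASTA goes through Biopython.  GFA1 support is minimal and self-contained:
segments are unitig sequences, links must carry a fixed (k-1)M overlap; the
graph is always rebuilt from segment sequence alone, so any annotations are
tolerated but never required.  Output FASTA wraps sequence at 80 columns for
bit-exact, diffable files.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import dna
from .graph import ORIGINAL, BidirectedDbg, build_graph
from .spss import Spss, duplicate_bitvectors

LINE_WIDTH = 80


class FormatError(ValueError):
    pass


def _open_maybe_gzip(path, mode: str = "rt"):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path) -> list[SeqRecord]:
    """Read a FASTA file (gzip detected by magic bytes), in file order."""
    records = []
    with _open_maybe_gzip(path) as fh:
        text = fh.read()
        if text.strip() and not text.lstrip().startswith(">"):
            line = text.splitlines()[0][:40]
            raise FormatError(f"not FASTA (line 1: {line!r})")
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            records.append(rec)
    return records


def _write_fasta(records: list[tuple[str, str]], path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), LINE_WIDTH):
                fh.write(seq[i : i + LINE_WIDTH] + "\n")


def write_spss(spss: Spss, path, with_bitvector: bool = False,
               bitvector_path=None) -> None:
    """Write an SPSS as FASTA with ids tig_0..tig_{SC-1}.

    With ``with_bitvector``, a sidecar text file (default: path + '.duplicates')
    gets one ASCII '0'/'1' line per tig, one character per k-mer position, '1'
    marking a k-mer whose canonical form occurred earlier in the output.
    """
    _write_fasta(
        [(f"tig_{i}", s) for i, s in enumerate(spss.strings)], path
    )
    if with_bitvector:
        bv_path = Path(bitvector_path) if bitvector_path else Path(
            str(path) + ".duplicates"
        )
        with open(bv_path, "w") as fh:
            for line in duplicate_bitvectors(spss):
                fh.write(line + "\n")


def read_spss(path, k: int) -> Spss:
    return Spss([str(rec.seq).upper() for rec in read_sequences(path)], k)


# -- GFA1 -------------------------------------------------------------------


def read_gfa(path, k: int) -> BidirectedDbg:
    """Read a GFA1 graph with fixed (k-1)M overlaps into a BidirectedDbg.

    Segments are taken as the sequence content and the graph is rebuilt from
    them (links are validated but identifications follow from the sequences
    themselves, which keeps the reader robust to any segment annotations).
    """
    segments: list[str] = []
    expected = f"{k - 1}M"
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3 or not fields[2] or fields[2] == "*":
                    raise FormatError(f"line {lineno}: S record without sequence")
                segments.append(fields[2].upper())
            elif tag == "L":
                if len(fields) < 6:
                    raise FormatError(f"line {lineno}: truncated L record")
                overlap = fields[5]
                if overlap != expected:
                    raise FormatError(
                        f"line {lineno}: overlap {overlap!r}, expected {expected!r}"
                    )
            # H and other records are ignored
    if not segments:
        raise FormatError("GFA contains no segments")
    return build_graph(segments, k)


def write_gfa(graph: BidirectedDbg, path) -> None:
    """Write the original biarcs of a graph as GFA1 (segments + (k-1)M links)."""
    km1 = graph.k - 1
    biarcs = graph.iter_biarcs(ORIGINAL)
    seg_name = {a: f"s{i}" for i, a in enumerate(biarcs)}
    # orientation of each doubled arc relative to its canonical segment
    orient: dict[int, tuple[str, str]] = {}
    for a in biarcs:
        arc = graph.arcs[a]
        orient[a] = (seg_name[a], "+")
        orient[arc.twin] = (seg_name[a], "-")
    lines = [f"H\tVN:Z:1.0"]
    for a in biarcs:
        lines.append(f"S\t{seg_name[a]}\t{graph.arc_label(a)}")
    links = set()
    for a in graph.arcs:
        if a.kind != ORIGINAL:
            continue
        for b_id in graph.out_arcs(a.head):
            b = graph.arcs[b_id]
            if b.kind != ORIGINAL:
                continue
            na, oa = orient[a.id]
            nb, ob = orient[b_id]
            # each link and its reverse-complement mirror are the same link
            mirror = (nb, "+" if ob == "-" else "-", na, "+" if oa == "-" else "-")
            if (na, oa, nb, ob) <= mirror:
                links.add((na, oa, nb, ob))
    for na, oa, nb, ob in sorted(links):
        lines.append(f"L\t{na}\t{oa}\t{nb}\t{ob}\t{km1}M")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
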