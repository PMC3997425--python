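"""Exact mapping of small-RNA sequences onto reference contigs, both strands.

A k-mer hash index (k = 16, the minimum read length) with full-length
verification is exact and sufficient at the contig sizes this pipeline
handles; minus-strand hits are reported in forward-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import revcomp_dna, to_dna
from .formats_io import SequenceRecord

__all__ = ["GenomeHit", "GenomeIndex", "build_index", "map_exact"]

KMER = 16


@dataclass(frozen=True)
class GenomeHit:
    """One exact occurrence of a read: 0-based half-open forward-strand span."""

    contig: str
    start: int
    end: int
    strand: str  # "+" or "-"
    seq: str     # the query, as given


class GenomeIndex:
    def __init__(self, contigs: Sequence[SequenceRecord]):
        if not contigs:
            raise ValueError("cannot index an empty contig set")
        self.contigs: dict[str, str] = {}
        for rec in contigs:
            if rec.id in self.contigs:
                raise ValueError(f"duplicate contig id {rec.id!r}")
            self.contigs[rec.id] = to_dna(rec.seq)
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for cid, seq in self.contigs.items():
            for i in range(0, len(seq) - KMER + 1):
                self._kmers.setdefault(seq[i : i + KMER], []).append((cid, i))

    def _occurrences(self, query_dna: str) -> list[tuple[str, int]]:
        if len(query_dna) < KMER:
            raise ValueError(f"query shorter than {KMER} nt")
        out = []
        for cid, pos in self._kmers.get(query_dna[:KMER], ()):
            if self.contigs[cid][pos : pos + len(query_dna)] == query_dna:
                out.append((cid, pos))
        return out

    def lookup(self, read: str) -> list[GenomeHit]:
        q = to_dna(read)
        n = len(q)
        hits: set[GenomeHit] = set()
        for cid, pos in self._occurrences(q):
            hits.add(GenomeHit(cid, pos, pos + n, "+", read))
        for cid, pos in self._occurrences(revcomp_dna(q)):
            hits.add(GenomeHit(cid, pos, pos + n, "-", read))
        return sorted(hits, key=lambda h: (h.contig, h.start, h.strand))


def build_index(contigs: Sequence[SequenceRecord]) -> GenomeIndex:
    """Build the exact-lookup index over the given contigs."""
    return GenomeIndex(contigs)


def map_exact(read: str, index: GenomeIndex) -> list[GenomeHit]:
    """All exact occurrences of ``read`` on both strands, sorted by locus."""
    return index.lookup(read)
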