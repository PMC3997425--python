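"""Nucleotide alphabet helpers shared across the pipeline.

Reads and duplex logic work on the RNA alphabet (U), genome matching on DNA
(T); the converters are total on {A,C,G,T,U,N} and case-insensitive.
"""

from __future__ import annotations

_RNA = str.maketrans("Tt", "Uu")
_DNA = str.maketrans("Uu", "Tt")
_COMP_DNA = str.maketrans("ACGTN", "TGCAN")
_COMP_RNA = str.maketrans("ACGUN", "UGCAN")

VALID_RNA = frozenset("ACGU")


def to_rna(seq: str) -> str:
    """Normalize to the upper-case RNA alphabet (T becomes U)."""
    return seq.upper().translate(_RNA)


def to_dna(seq: str) -> str:
    """Normalize to the upper-case DNA alphabet (U becomes T)."""
    return seq.upper().translate(_DNA)


def revcomp_dna(seq: str) -> str:
    return to_dna(seq).translate(_COMP_DNA)[::-1]


def revcomp_rna(seq: str) -> str:
    return to_rna(seq).translate(_COMP_RNA)[::-1]


def is_wc_or_wobble(a: str, b: str) -> bool:
    """True if RNA bases a and b form a Watson-Crick or G:U wobble pair."""
    pair = a + b
    return pair in ("AU", "UA", "GC", "CG", "GU", "UG")


def pair_score(a: str, b: str) -> int:
    """Stability score of an RNA base pair: GC=3, AU=2, GU=1, else 0."""
    pair = a + b
    if pair in ("GC", "CG"):
        return 3
    if pair in ("AU", "UA"):
        return 2
    if pair in ("GU", "UG"):
        return 1
    return 0


def gc_percent(seq: str) -> float:
    s = seq.upper()
    if not s:
        return 0.0
    return 100.0 * sum(1 for c in s if c in "GC") / len(s)
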