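"""Elimination pipeline for raw small-RNA libraries.

Raw reads pass through adapter trimming and a fixed first-match cascade of
filters — length (16–30 nt), low complexity, invalid characters, t/rRNA
contaminants — so every read is counted in exactly one elimination category.
Survivors are collapsed to unique sequences with per-library counts (the
"putative small RNA population") and summarised as a length distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd

from ._seq import VALID_RNA, revcomp_dna, to_dna, to_rna
from .formats_io import EliminationSummary

__all__ = [
    "UniqueRead",
    "trim_adapter",
    "filter_length",
    "is_invalid",
    "is_low_complexity",
    "ContaminantFilter",
    "filter_contaminants",
    "collapse_unique",
    "elimination_summary",
    "length_distribution",
    "run_elimination",
]

MIN_LEN = 16
MAX_LEN = 30


@dataclass
class UniqueRead:
    """A distinct cleaned sequence with per-library redundant counts."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def trim_adapter(
    seq: str,
    adapter_3p: str,
    seed_len: int = 8,
    require_adapter: bool = True,
) -> str | None:
    """Cut a read at the left-most exact match of the adapter's seed.

    Returns the insert (possibly empty — later length filtering rejects it),
    or None when no adapter is found and ``require_adapter`` is set.
    """
    if not adapter_3p:
        raise ValueError("adapter sequence must be non-empty")
    seed = adapter_3p[: seed_len]
    idx = seq.find(seed)
    if idx < 0:
        return None if require_adapter else seq
    return seq[:idx]


def filter_length(
    reads: Iterable[str], min_len: int = MIN_LEN, max_len: int = MAX_LEN
) -> tuple[list[str], int]:
    """Keep reads with min_len <= length <= max_len; report the removed tally."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    kept, removed = [], 0
    for r in reads:
        if min_len <= len(r) <= max_len:
            kept.append(r)
        else:
            removed += 1
    return kept, removed


def is_invalid(seq: str) -> bool:
    """True if the read contains anything outside {A,C,G,U} after RNA normalization."""
    s = to_rna(seq)
    return not s or any(c not in VALID_RNA for c in s)


def is_low_complexity(seq: str) -> bool:
    """Simple-sequence-repeat / tandem-repeat test.

    A read is low complexity when the occurrences of a single k-mer (k <= 3)
    cover at least 80% of its length.  Mononucleotide runs and di/trinucleotide
    SSRs are the intended catch.
    """
    s = seq.upper()
    n = len(s)
    if n == 0:
        return False
    for k in (1, 2, 3):
        if k > n:
            break
        counts: dict[str, int] = {}
        for i in range(n - k + 1):
            w = s[i : i + k]
            counts[w] = counts.get(w, 0) + 1
        for w, c in counts.items():
            if c * k < 0.8 * n:  # coverage cannot reach the threshold
                continue
            covered = [False] * n
            i = s.find(w)
            while i != -1:
                covered[i : i + k] = [True] * k
                i = s.find(w, i + 1)
            if sum(covered) >= 0.8 * n:
                return True
    return False


class ContaminantFilter:
    """Exact-substring membership test against t/rRNA references (both strands).

    Indexes every window of length 16–30 of each contaminant and of its
    reverse complement, so lookup per read is O(1).
    """

    def __init__(self, contaminants: Iterable[str]):
        self._windows: set[str] = set()
        for ref in contaminants:
            ref_dna = to_dna(ref)
            for strand_seq in (ref_dna, revcomp_dna(ref_dna)):
                n = len(strand_seq)
                for w in range(MIN_LEN, MAX_LEN + 1):
                    for i in range(0, n - w + 1):
                        self._windows.add(strand_seq[i : i + w])

    def __contains__(self, read: str) -> bool:
        return to_dna(read) in self._windows

    def __len__(self) -> int:
        return len(self._windows)


def filter_contaminants(
    reads: Iterable[str], contaminant_set: ContaminantFilter | Iterable[str]
) -> tuple[list[str], int]:
    """Remove reads occurring as exact substrings of a contaminant (either strand)."""
    if not isinstance(contaminant_set, ContaminantFilter):
        contaminant_set = ContaminantFilter(contaminant_set)
    if len(contaminant_set) == 0:
        warnings.warn("empty contaminant set: all reads pass through")
        reads = list(reads)
        return reads, 0
    kept, removed = [], 0
    for r in reads:
        if r in contaminant_set:
            removed += 1
        else:
            kept.append(r)
    return kept, removed


def collapse_unique(per_library_reads: Mapping[str, Sequence[str]]) -> list[UniqueRead]:
    """Collapse cleaned per-library reads into unique sequences with counts.

    Sequences are RNA-normalized; the result is ordered by descending total
    count, ties broken lexicographically, so downstream naming is stable.
    """
    merged: dict[str, dict[str, int]] = {}
    for lib, reads in per_library_reads.items():
        counter = Counter(to_rna(r) for r in reads)
        for seq, n in counter.items():
            merged.setdefault(seq, {})[lib] = merged.get(seq, {}).get(lib, 0) + n
    unique = [UniqueRead(seq=s, counts=c) for s, c in merged.items()]
    unique.sort(key=lambda u: (-u.total_count, u.seq))
    return unique


def elimination_summary(stage_tallies: Mapping[str, tuple[int, int]]) -> EliminationSummary:
    """Assemble an EliminationSummary from (redundant, unique) stage tallies.

    ``stage_tallies`` must carry total, length_filtered, low_complexity,
    invalid and rRNA_tRNA; the putative population is derived and the
    conservation identity enforced.
    """
    redundant: dict[str, int] = {}
    unique: dict[str, int] = {}
    for cat in ("total", "length_filtered", "low_complexity", "invalid", "rRNA_tRNA"):
        if cat not in stage_tallies:
            raise ValueError(f"missing stage tally {cat!r}")
        r, u = stage_tallies[cat]
        if r < 0 or u < 0:
            raise ValueError(f"negative tally for {cat!r}")
        redundant[cat], unique[cat] = int(r), int(u)
    for tally in (redundant, unique):
        tally["putative_population"] = tally["total"] - (
            tally["length_filtered"]
            + tally["low_complexity"]
            + tally["invalid"]
            + tally["rRNA_tRNA"]
        )
    if "genome_mapped" in stage_tallies:
        r, u = stage_tallies["genome_mapped"]
        redundant["genome_mapped"], unique["genome_mapped"] = int(r), int(u)
    summary = EliminationSummary(redundant=redundant, unique=unique)
    summary.validate()
    return summary


def length_distribution(unique_reads: Sequence[UniqueRead]) -> pd.DataFrame:
    """Per-length tallies and percentages (redundant and unique views), 16–30 nt."""
    lengths = range(MIN_LEN, MAX_LEN + 1)
    red = {l: 0 for l in lengths}
    uni = {l: 0 for l in lengths}
    for u in unique_reads:
        l = len(u.seq)
        if l not in red:
            raise ValueError(f"read of length {l} outside the {MIN_LEN}-{MAX_LEN} window")
        red[l] += u.total_count
        uni[l] += 1
    total_red = sum(red.values()) or 1
    total_uni = sum(uni.values()) or 1
    return pd.DataFrame(
        {
            "length": list(lengths),
            "redundant_count": [red[l] for l in lengths],
            "unique_count": [uni[l] for l in lengths],
            "redundant_pct": [100.0 * red[l] / total_red for l in lengths],
            "unique_pct": [100.0 * uni[l] / total_uni for l in lengths],
        }
    )


def run_elimination(
    per_library_reads: Mapping[str, Sequence[str]],
    contaminants: Iterable[str] = (),
    adapter_3p: str | None = None,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[list[UniqueRead], EliminationSummary]:
    """Run the full cascade and account every read in exactly one category.

    Category priority: length > low-complexity > invalid > t/rRNA.  Tallies
    are kept for redundant reads and for unique sequences (a unique sequence
    is counted in the category its copies fall in; all copies of a sequence
    share one category because the filters are sequence-deterministic).
    """
    cfilter = ContaminantFilter(contaminants)
    cleaned: dict[str, list[str]] = {}
    red = {c: 0 for c in ("total", "length_filtered", "low_complexity", "invalid", "rRNA_tRNA")}
    seq_category: dict[str, str] = {}

    def categorize(seq: str) -> str:
        if not (min_len <= len(seq) <= max_len):
            return "length_filtered"
        if is_low_complexity(seq):
            return "low_complexity"
        if is_invalid(seq):
            return "invalid"
        if len(cfilter) and seq in cfilter:
            return "rRNA_tRNA"
        return "putative"

    for lib, reads in per_library_reads.items():
        kept: list[str] = []
        for raw in reads:
            seq = to_rna(raw)
            if adapter_3p is not None:
                trimmed = trim_adapter(seq, to_rna(adapter_3p))
                if trimmed is None:
                    continue  # no adapter: not part of the accounted total
                seq = trimmed
            red["total"] += 1
            cat = seq_category.get(seq)
            if cat is None:
                cat = categorize(seq)
                seq_category[seq] = cat
            if cat == "putative":
                kept.append(seq)
            else:
                red[cat] += 1
        cleaned[lib] = kept

    uni = {c: 0 for c in red}
    for seq, cat in seq_category.items():
        uni["total"] += 1
        if cat != "putative":
            uni[cat] += 1

    unique_reads = collapse_unique(cleaned)
    summary = elimination_summary(
        {c: (red[c], uni[c]) for c in ("total", "length_filtered", "low_complexity", "invalid", "rRNA_tRNA")}
    )
    return unique_reads, summary
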