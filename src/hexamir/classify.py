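"""Categorisation of accepted miRNAs against a reference catalog.

A mature sequence identical to a catalog entry is *known*; 1-2 mismatches
from its best entry make it a *variant*; 3 or more (or no match at all) make
it *novel*.  Novel miRNAs whose predicted star strand is itself present in
the cleaned read population are *true novel* (named tae_1, tae_2, ...);
the rest are *candidate novel* (tae_C1, ...).  Cross-species conservation is
assessed by exact substring mapping of the mature onto each species'
sequence set, both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import revcomp_dna, to_dna, to_rna
from .formats_io import SequenceRecord
from .preprocess import UniqueRead

__all__ = [
    "MiRNARecord",
    "match_reference",
    "detect_star",
    "assign_names",
    "family_from_name",
    "map_conservation",
    "classify_mirnas",
]

CATEGORIES = ("known", "variant", "true_novel", "candidate_novel")


@dataclass
class MiRNARecord:
    mature: str
    star: str | None = None
    category: str | None = None  # one of CATEGORIES
    name: str | None = None
    family: str | None = None
    best_match: str | None = None
    best_mismatches: int | None = None
    star_detected: bool = False
    loci: list = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def _ungapped_mismatches(a: str, b: str) -> int:
    """Mismatches under the best ungapped offset alignment.

    Equal lengths compare end-to-end; otherwise the shorter slides along the
    longer and every overhanging base counts 1.
    """
    if len(a) == len(b):
        return sum(1 for x, y in zip(a, b) if x != y)
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    ls, ll = len(short), len(long_)
    best = ls + ll  # worse than any alignment
    for off in range(0, ll - ls + 1):
        mm = sum(1 for i in range(ls) if short[i] != long_[off + i]) + (ll - ls)
        best = min(best, mm)
    return best


def match_reference(
    mature: str, catalog: Sequence[SequenceRecord]
) -> tuple[str, str | None, int | None]:
    """Best catalog match and the category it implies.

    Returns (category, best_match_id, mismatches); category is 'known',
    'variant' or 'novel' ('novel' still needs the star split downstream).
    """
    m = to_rna(mature)
    best_id, best_mm = None, None
    for entry in catalog:
        mm = _ungapped_mismatches(m, to_rna(entry.seq))
        if best_mm is None or mm < best_mm or (mm == best_mm and entry.id < best_id):
            best_id, best_mm = entry.id, mm
    if best_mm is None:
        return "novel", None, None
    if best_mm == 0:
        return "known", best_id, 0
    if best_mm <= 2:
        return "variant", best_id, best_mm
    return "novel", best_id, best_mm


def detect_star(star_seq: str | None, unique_reads: Iterable[UniqueRead]) -> bool:
    """True iff the predicted star occurs exactly among the cleaned unique reads."""
    if star_seq is None:
        return False
    target = to_rna(star_seq)
    if isinstance(unique_reads, (set, frozenset, dict)):
        return target in unique_reads
    return any(to_rna(u.seq) == target for u in unique_reads)


_FAMILY_RE = re.compile(r"miR[a-zA-Z]*?(\d+)", re.IGNORECASE)


def family_from_name(name: str) -> str:
    """Strip species prefix and letter/arm suffixes: zma-miR156i-5p -> MIR156."""
    m = _FAMILY_RE.search(name)
    if m:
        return f"MIR{m.group(1)}"
    return name


def assign_names(records: Sequence[MiRNARecord]) -> list[MiRNARecord]:
    """Deterministic naming: tae_N for true novels, tae_CN for candidates.

    Ordering within each novel class is by descending total count, ties by
    mature sequence.  Known and variant records keep their catalog-derived
    names; families are inherited from the catalog match where available.
    """
    def order(recs):
        return sorted(recs, key=lambda r: (-r.total_count, r.mature))

    for rec in records:
        if rec.category in ("known", "variant") and rec.best_match:
            rec.name = rec.best_match if rec.category == "known" else None
            rec.family = family_from_name(rec.best_match)
    for i, rec in enumerate(order([r for r in records if r.category == "true_novel"]), 1):
        rec.name = f"tae_{i}"
        rec.family = rec.family or rec.name
    for i, rec in enumerate(
        order([r for r in records if r.category == "candidate_novel"]), 1
    ):
        rec.name = f"tae_C{i}"
        rec.family = rec.family or rec.name
    for i, rec in enumerate(order([r for r in records if r.category == "variant"]), 1):
        rec.name = f"tae_v{i}({rec.best_match})"
    return list(records)


def classify_mirnas(
    mirna_seqs: Sequence[tuple[str, str | None, dict, list]],
    catalog: Sequence[SequenceRecord],
    unique_reads: Sequence[UniqueRead],
) -> list[MiRNARecord]:
    """Full classification: catalog match, star detection, category, names.

    ``mirna_seqs`` carries (mature, predicted_star, per-library counts, loci)
    tuples, one per sequence-level miRNA.
    """
    read_set = {to_rna(u.seq) for u in unique_reads}
    records = []
    for mature, star, counts, loci in mirna_seqs:
        category, best, mm = match_reference(mature, catalog)
        star_found = detect_star(star, read_set)
        if category == "novel":
            category = "true_novel" if star_found else "candidate_novel"
        rec = MiRNARecord(
            mature=to_rna(mature),
            star=to_rna(star) if star else None,
            category=category,
            best_match=best,
            best_mismatches=mm,
            star_detected=star_found,
            loci=list(loci),
            counts=dict(counts),
        )
        records.append(rec)
    return assign_names(records)


def map_conservation(
    records: Sequence[MiRNARecord],
    species_sequence_sets: Mapping[str, Sequence[SequenceRecord]],
) -> pd.DataFrame:
    """Boolean presence matrix: mature maps exactly (either strand) per species."""
    if not species_sequence_sets:
        raise ValueError("at least one species sequence set required")
    species = list(species_sequence_sets)
    rows = {}
    for rec in records:
        mature_dna = to_dna(rec.mature)
        rc = revcomp_dna(mature_dna)
        present = []
        for sp in species:
            found = any(
                mature_dna in to_dna(s.seq) or rc in to_dna(s.seq)
                for s in species_sequence_sets[sp]
            )
            present.append(found)
        rows[rec.name or rec.mature] = present
    return pd.DataFrame.from_dict(rows, orient="index", columns=species)


def conservation_summary(
    records: Sequence[MiRNARecord], matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-species presence totals by category (known / true novel / candidate novel)."""
    by_name = {r.name or r.mature: r for r in records}
    cats = ("known", "variant", "true_novel", "candidate_novel")
    out = pd.DataFrame(0, index=list(cats), columns=matrix.columns)
    for name, row in matrix.iterrows():
        rec = by_name.get(name)
        if rec is None or rec.category not in cats:
            continue
        out.loc[rec.category] += row.astype(int)
    return out
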