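"""Reading and writing of the standard formats the pipeline touches.

FASTA/FASTQ parsing is strict: duplicate identifiers, empty sequences and
malformed records raise :class:`ParseError` naming the offending line, which
is the behaviour the elimination pipeline relies on to refuse corrupt input
early.  The module also ships desk-scale fixture tables (read-accounting
summary and the true-novel miRNA list) used by the ``fixtures-check``
subcommand and the acceptance suite.
"""

from __future__ import annotations

import gzip
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SequenceRecord",
    "EliminationSummary",
    "TrueNovelFixtureRecord",
    "ParseError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "load_table1_fixture",
    "load_table2_fixture",
    "write_gff3",
    "write_newick",
    "write_tsv",
    "read_tsv",
]

ELIMINATION_CATEGORIES = (
    "total",
    "length_filtered",
    "low_complexity",
    "invalid",
    "rRNA_tRNA",
    "putative_population",
    "genome_mapped",
)


class ParseError(ValueError):
    """Malformed input file; message carries the 1-based line number."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional per-base quality."""

    id: str
    seq: str
    quality: str | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()


@dataclass
class EliminationSummary:
    """Per-category read tallies (redundant and unique) of the cleaning pipeline.

    Conservation invariant: putative = total - (length + low-complexity +
    invalid + rRNA/tRNA), independently for redundant and unique tallies.
    """

    redundant: dict[str, int] = field(default_factory=dict)
    unique: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for name, tally in (("redundant", self.redundant), ("unique", self.unique)):
            for cat in ELIMINATION_CATEGORIES[:-1]:
                if cat not in tally:
                    raise ValueError(f"{name} tally missing category {cat!r}")
                if tally[cat] < 0:
                    raise ValueError(f"{name} count for {cat!r} is negative")
            eliminated = sum(
                tally[c]
                for c in ("length_filtered", "low_complexity", "invalid", "rRNA_tRNA")
            )
            if tally["putative_population"] != tally["total"] - eliminated:
                raise ValueError(
                    f"{name} tallies violate conservation: "
                    f"{tally['total']} - {eliminated} != {tally['putative_population']}"
                )

    def to_frame(self) -> pd.DataFrame:
        cats = [c for c in ELIMINATION_CATEGORIES if c in self.redundant]
        return pd.DataFrame(
            {
                "category": cats,
                "redundant": [self.redundant[c] for c in cats],
                "unique": [self.unique[c] for c in cats],
            }
        )


@dataclass
class TrueNovelFixtureRecord:
    """One row of the true-novel miRNA table: mature/star pair plus target call."""

    name: str
    mature: str
    length: int
    star: str
    target: str
    action: str  # C (cleavage), T (translational repression), NA (no target)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into records; U and T are both accepted and preserved."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"line {header_line}: record {header!r} has empty sequence")
        records.append(SequenceRecord(header, seq))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                if header in seen:
                    raise ParseError(f"line {lineno}: duplicate id {header!r}")
                seen.add(header)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence before first header")
                chunks.append(line)
    flush()
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Parse 4-line FASTQ records; sequence/quality length mismatch is an error."""
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(f"line {len(lines)}: truncated FASTQ record")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError(f"line {lineno}: FASTQ header must start with '@'")
        if not plus.startswith("+"):
            raise ParseError(f"line {lineno + 2}: expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(
                f"line {lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        if not seq:
            raise ParseError(f"line {lineno + 1}: empty sequence")
        records.append(SequenceRecord(head[1:].split()[0], seq, qual))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def _fixture_path(name: str) -> Path:
    return Path(str(importlib.resources.files("hexamir").joinpath("data", name)))


def load_table1_fixture() -> EliminationSummary:
    """Packaged read-accounting fixture (pooled eight-library elimination tallies)."""
    path = _fixture_path("table1.tsv")
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["category", "redundant", "unique"]:
        raise ValueError(f"fixture {path} has unexpected columns {list(df.columns)}")
    summary = EliminationSummary(
        redundant=dict(zip(df["category"], df["redundant"].astype(int))),
        unique=dict(zip(df["category"], df["unique"].astype(int))),
    )
    summary.validate()
    return summary


def load_table2_fixture() -> list[TrueNovelFixtureRecord]:
    """Packaged list of the 49 true-novel miRNAs with star sequences and targets."""
    path = _fixture_path("table2.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        if not isinstance(row.star, str) or not row.star:
            raise ValueError(f"fixture row {row.name}: missing star sequence")
        rec = TrueNovelFixtureRecord(
            name=row.name,
            mature=row.mature,
            length=int(row.length),
            star=row.star,
            target=row.target,
            action=row.action,
        )
        if rec.length != len(rec.mature):
            raise ValueError(
                f"fixture row {rec.name}: stated length {rec.length} != {len(rec.mature)}"
            )
        records.append(rec)
    return records


def write_gff3(features: Sequence[dict], path: str | Path) -> None:
    """Emit GFF3 features.

    Each feature dict needs: contig, start, end (1-based inclusive), strand,
    type; optional: id, parent, score, attributes (dict).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            start, end = int(feat["start"]), int(feat["end"])
            if start < 1 or end < start:
                raise ValueError(f"GFF3 coordinates must be 1-based: {start}..{end}")
            attrs = dict(feat.get("attributes", {}))
            if "id" in feat:
                attrs = {"ID": feat["id"], **attrs}
            if "parent" in feat:
                attrs["Parent"] = feat["parent"]
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            score = feat.get("score", ".")
            fh.write(
                "\t".join(
                    [
                        str(feat["contig"]),
                        "hexamir",
                        feat["type"],
                        str(start),
                        str(end),
                        str(score),
                        feat["strand"],
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )


def write_newick(newick: str, path: str | Path) -> None:
    newick = newick.strip()
    if not newick.endswith(";"):
        newick += ";"
    with open(path, "w") as fh:
        fh.write(newick + "\n")


def write_tsv(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
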