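"""End-to-end orchestration: clean -> map -> discover -> classify -> express -> targets.

A PipelineConfig gathers the file paths and the numeric screening constants
(length bounds 16/30, 100-nt precursor flanks, 4-mismatch duplex cap, 2-nt
overhangs, 1-2-mismatch variant band, >=3-mismatch novel threshold, log2
fold-change threshold 1, target expectation cutoff 3.0).  ``run_all`` writes
every stage artifact plus a JSON run report and is deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import discovery as _discovery
from . import expression as _expression
from . import formats_io as io
from . import genome_map as _gmap
from . import preprocess as _pre
from . import targets as _targets

logger = logging.getLogger("hexamir")

__all__ = ["PipelineConfig", "ConfigError", "run_all"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


@dataclass
class PipelineConfig:
    libraries: dict[str, str] = field(default_factory=dict)  # library id -> FASTQ/FASTA
    genome: str = ""
    contaminants: str | None = None
    catalog: str | None = None
    transcriptome: str | None = None
    outdir: str = "hexamir_out"
    adapter_3p: str | None = None
    min_len: int = 16
    max_len: int = 30
    flank: int = 100
    mismatch_cap: int = 4
    overhang: int = 2
    variant_band: tuple[int, int] = (1, 2)
    novel_threshold: int = 3
    de_threshold_log2: float = 1.0
    target_cutoff: float = 3.0
    detection_min_count: int = 1
    control_library: str = "C"
    contrast_libraries: tuple[str, ...] = ("HS", "SS", "WDS")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.variant_band, list):
            cfg.variant_band = tuple(cfg.variant_band)
        if isinstance(cfg.contrast_libraries, list):
            cfg.contrast_libraries = tuple(cfg.contrast_libraries)
        return cfg

    def validate(self) -> None:
        if not self.libraries:
            raise ConfigError("no input libraries configured")
        for lib, path in self.libraries.items():
            if not Path(path).exists():
                raise ConfigError(f"library {lib!r}: path {path} does not exist")
        if not self.genome or not Path(self.genome).exists():
            raise ConfigError(f"genome path {self.genome!r} does not exist")
        for name in ("contaminants", "catalog", "transcriptome"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path {p!r} does not exist")
        for name in ("min_len", "max_len", "flank", "mismatch_cap", "overhang",
                     "novel_threshold", "detection_min_count"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_len > self.max_len:
            raise ConfigError("min_len must not exceed max_len")
        if self.de_threshold_log2 <= 0 or self.target_cutoff <= 0:
            raise ConfigError("thresholds must be positive")


def _read_library(path: str) -> list[str]:
    p = Path(path)
    suffixes = {s.lower() for s in p.suffixes}
    if suffixes & {".fastq", ".fq"}:
        return [r.seq for r in io.read_fastq(p)]
    return [r.seq for r in io.read_fasta(p)]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage, write artifacts under ``config.outdir``, return the report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {k: v for k, v in asdict(config).items()}}

    # ---- clean ----------------------------------------------------------
    logger.info("stage clean: elimination pipeline")
    per_lib = {lib: _read_library(path) for lib, path in config.libraries.items()}
    contaminants = (
        [r.seq for r in io.read_fasta(config.contaminants)] if config.contaminants else []
    )
    unique_reads, summary = _pre.run_elimination(
        per_lib,
        contaminants=contaminants,
        adapter_3p=config.adapter_3p,
        min_len=config.min_len,
        max_len=config.max_len,
    )
    lengths = _pre.length_distribution(unique_reads)
    io.write_tsv(summary.to_frame(), outdir / "elimination_summary.tsv")
    io.write_tsv(lengths, outdir / "length_distribution.tsv")
    io.write_fasta(
        (io.SequenceRecord(f"seq{i + 1}_x{u.total_count}", u.seq)
         for i, u in enumerate(unique_reads)),
        outdir / "unique_reads.fasta",
    )
    report["elimination"] = {
        "redundant": summary.redundant,
        "unique": summary.unique,
    }

    # ---- map ------------------------------------------------------------
    logger.info("stage map: exact genome mapping of %d unique reads", len(unique_reads))
    index = _gmap.build_index(io.read_fasta(config.genome))
    mapped = []
    n_hits_red = 0
    for u in unique_reads:
        hits = index.lookup(u.seq)
        if hits:
            mapped.append((u, hits))
            n_hits_red += u.total_count
    report["mapping"] = {
        "unique_mapped": len(mapped),
        "redundant_mapped": n_hits_red,
    }
    hit_rows = [
        {"contig": h.contig, "start": h.start, "end": h.end, "strand": h.strand,
         "seq": u.seq, "total_count": u.total_count}
        for u, hits in mapped for h in hits
    ]
    io.write_tsv(pd.DataFrame(hit_rows), outdir / "genome_hits.tsv")

    # ---- discover -------------------------------------------------------
    logger.info("stage discover: folding %d candidate loci", len(hit_rows))
    candidates = _discovery.discover_hairpins(
        [u for u, _ in mapped], index, flank=config.flank
    )
    deduped = _discovery.deduplicate_loci(candidates)
    report["discovery"] = {
        "candidates": len(candidates),
        "accepted": sum(1 for c in candidates if c.accepted),
        "loci_after_dedup": len(deduped),
    }
    gff_feats = []
    for i, c in enumerate(deduped, 1):
        prec = c.precursor
        if prec.strand == "+":
            gs = prec.start + c.trimmed_start
            ge = prec.start + c.trimmed_end
        else:
            ge = prec.end - c.trimmed_start
            gs = prec.end - c.trimmed_end
        gff_feats.append(
            {"contig": prec.contig, "type": "miRNA_primary_transcript",
             "start": gs + 1, "end": ge, "strand": prec.strand,
             "id": f"hairpin_{i}", "attributes": {"mature": c.mature_seq}}
        )
    io.write_gff3(gff_feats, outdir / "hairpins.gff3")
    io.write_fasta(
        (io.SequenceRecord(f"hairpin_{i + 1}", c.trimmed_seq)
         for i, c in enumerate(deduped)),
        outdir / "precursors.fasta",
    )
    hairpin_rows = [
        {"mature": c.mature_seq, "star": c.duplex.star_seq,
         "mismatches": c.duplex.mismatches, "contig": c.precursor.contig,
         "strand": c.precursor.strand,
         "precursor_len": c.trimmed_end - c.trimmed_start,
         "gc_pct": round(c.gc_content, 2),
         "structure": c.fold.structure[c.trimmed_start:c.trimmed_end]}
        for c in deduped
    ]
    io.write_tsv(pd.DataFrame(hairpin_rows), outdir / "hairpins.tsv")
    if deduped:
        report["precursor_stats"] = _discovery.precursor_stats(deduped)

    # ---- classify -------------------------------------------------------
    logger.info("stage classify: %d sequence-level miRNAs", len(deduped))
    by_seq: dict[str, dict] = {}
    for c in deduped:
        entry = by_seq.setdefault(
            c.mature_seq,
            {"star": c.duplex.star_seq, "counts": c.read_counts, "loci": []},
        )
        entry["loci"].append(
            (c.precursor.contig, c.precursor.start, c.precursor.end, c.precursor.strand)
        )
    catalog = io.read_fasta(config.catalog) if config.catalog else []
    records = _classify.classify_mirnas(
        [(seq, d["star"], d["counts"], d["loci"]) for seq, d in by_seq.items()],
        catalog,
        unique_reads,
    )
    cat_counts = {c: sum(1 for r in records if r.category == c) for c in _classify.CATEGORIES}
    report["classification"] = cat_counts
    class_rows = [
        {"name": r.name, "category": r.category, "mature": r.mature, "star": r.star,
         "family": r.family, "best_match": r.best_match,
         "best_mismatches": r.best_mismatches, "star_detected": r.star_detected,
         "total_count": r.total_count, "n_loci": len(r.loci)}
        for r in records
    ]
    io.write_tsv(pd.DataFrame(class_rows), outdir / "classification.tsv")

    # ---- express --------------------------------------------------------
    logger.info("stage express: digital expression over %d libraries", len(per_lib))
    lib_ids = list(config.libraries)
    counts = pd.DataFrame(
        {lib: [r.counts.get(lib, 0) for r in records] for lib in lib_ids},
        index=[r.name for r in records],
    )
    # per-library putative population size = cleaned redundant reads in that library
    totals = {lib: sum(u.counts.get(lib, 0) for u in unique_reads) for lib in lib_ids}
    matrix = _expression.tpm_normalize(counts, totals)
    io.write_tsv(matrix.tpm.round(3), outdir / "tpm.tsv", index=True)
    contrasts = {
        lib: (lib, config.control_library)
        for lib in config.contrast_libraries
        if lib in lib_ids and config.control_library in lib_ids
    }
    de_names: list[str] = []
    if contrasts:
        fc, status = _expression.log2_fold_change(matrix.tpm, contrasts)
        io.write_tsv(fc.round(4), outdir / "fold_change.tsv", index=True)
        de = _expression.select_de(fc, threshold=config.de_threshold_log2)
        de_names = list(de.index)
        report["differential_expression"] = {
            "contrasts": {k: list(v) for k, v in contrasts.items()},
            "n_selected": len(de_names),
            "selected": de_names,
        }
    detected = matrix.detected(config.detection_min_count)
    tissue_libs = [l for l in ("shoot", "root", "mature_leaf", "spikelet") if l in lib_ids]
    if len(tissue_libs) >= 2:
        regions = _expression.venn_partition(detected, tissue_libs)
        venn_rows = [
            {"region": "+".join(sorted(k)), "count": v} for k, v in sorted(
                regions.items(), key=lambda kv: (len(kv[0]), "+".join(sorted(kv[0])))
            )
        ]
        io.write_tsv(pd.DataFrame(venn_rows), outdir / "venn_tissue.tsv")
        report["venn_tissue"] = {"+".join(sorted(k)): v for k, v in regions.items()}
    stress_libs = [l for l in config.contrast_libraries if l in lib_ids]
    if tissue_libs and stress_libs:
        meta = pd.DataFrame(
            {
                "tissue": detected[tissue_libs].any(axis=1),
                "stress": detected[stress_libs].any(axis=1),
            }
        )
        overlap = _expression.venn_partition(meta, ["tissue", "stress"])
        report["venn_tissue_vs_stress"] = {
            "+".join(sorted(k)): v for k, v in overlap.items()
        }
    cluster_cols = [c for c in [config.control_library, *config.contrast_libraries] if c in lib_ids]
    if de_names and len(cluster_cols) >= 2:
        sub = matrix.tpm.loc[de_names, cluster_cols]
        sub = sub.loc[(sub > 0).any(axis=1)]
        if len(sub) >= 2:
            dendro = _expression.cluster_uncentered_average(sub, axis="rows")
            io.write_newick(dendro.to_newick(), outdir / "mirna_dendrogram.newick")
            samples = _expression.cluster_uncentered_average(sub, axis="columns")
            io.write_newick(samples.to_newick(), outdir / "sample_dendrogram.newick")
            report["sample_dendrogram"] = samples.to_newick()

    # ---- targets --------------------------------------------------------
    target_rows = []
    if config.transcriptome:
        transcriptome = io.read_fasta(config.transcriptome)
        logger.info("stage targets: scanning %d transcripts", len(transcriptome))
        for r in records:
            hits = _targets.scan_transcripts(
                r.mature, transcriptome, cutoff=config.target_cutoff,
                mirna_name=r.name or r.mature,
            )
            for h in hits:
                top, mid, bottom = h.alignment.rows()
                target_rows.append(
                    {"mirna": h.mirna_name, "transcript": h.transcript_id,
                     "start": h.start, "end": h.end, "penalty": h.penalty,
                     "mode": h.mode,
                     "cleavage": "NA" if h.cleavage is None else f"{h.cleavage[0]}-{h.cleavage[1]}",
                     "aln_mirna": top, "aln_pairing": mid, "aln_site": bottom}
                )
        io.write_tsv(pd.DataFrame(target_rows), outdir / "targets.tsv")
        report["targets"] = {"n_hits": len(target_rows)}

    report["seed"] = config.seed
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
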