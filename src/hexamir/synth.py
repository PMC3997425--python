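"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates an eight-library wheat-style small-RNA experiment:
four tissue libraries (shoot, root, mature_leaf, spikelet), an unstressed
control and three abiotic-stress libraries (heat, salt, water deficit).
Reads 16-40 nt are dominated by 21-24-nt species; MIR hairpins are planted
in random genomic background with asymmetric mature/star abundance; t/rRNA
contaminants, low-complexity junk and N-containing invalid reads provide the
elimination-pipeline categories; a reference catalog carries exact copies
(known), 1-2-mismatch homologs (variants) and omissions (novel); and
transcripts carry near-complementary target sites of designed penalty
classes.  Every operation takes an explicit seed; reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp_dna, revcomp_rna, to_dna, to_rna
from .discovery import evaluate_hairpin, extract_precursor, fold
from .formats_io import SequenceRecord
from .genome_map import GenomeHit
from .preprocess import is_low_complexity
from .targets import score_site

__all__ = [
    "PlantedHairpin",
    "PlantedSite",
    "TruthSet",
    "TISSUE_LIBRARIES",
    "STRESS_LIBRARIES",
    "ALL_LIBRARIES",
    "DEFAULT_PROPORTIONS",
    "make_genome",
    "simulate_libraries",
    "make_catalog",
    "make_transcriptome",
]

TISSUE_LIBRARIES = ("shoot", "root", "mature_leaf", "spikelet")
STRESS_LIBRARIES = ("HS", "SS", "WDS")
ALL_LIBRARIES = TISSUE_LIBRARIES + ("C",) + STRESS_LIBRARIES

# miRNAs are a modest fraction of a plant sRNA library's putative population;
# keeping them so preserves TPM compositional stability, so planted
# fold-change multipliers stay recoverable from normalised expression
DEFAULT_PROPORTIONS = {
    "mirna": 0.12,
    "contaminant": 0.25,
    "degradation": 0.53,
    "junk_length": 0.05,
    "invalid": 0.05,
}

# empirically plant-like read-length weights for the degradation background,
# peaked at 24 nt with secondary 21-23-nt mass
_DEG_LENGTHS = list(range(16, 31))
_DEG_WEIGHTS = np.array(
    [0.02, 0.02, 0.02, 0.03, 0.05, 0.10, 0.08, 0.12, 0.35, 0.05, 0.04, 0.04, 0.03, 0.03, 0.02]
)
_DEG_WEIGHTS = _DEG_WEIGHTS / _DEG_WEIGHTS.sum()

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedHairpin:
    name: str
    contig: str
    mature_start: int  # 0-based genomic start of the mature, forward strand
    mature: str        # RNA
    star: str          # RNA; what the canonical-register star prediction returns
    loop_len: int
    arm_mutations: int
    category: str      # known | variant | true_novel | candidate_novel
    star_ratio: float  # star:mature abundance ratio, 0 for candidate novels
    weight: float      # relative mature abundance
    multipliers: dict[str, float] = field(default_factory=dict)

    @property
    def mature_end(self) -> int:
        return self.mature_start + len(self.mature)


@dataclass
class PlantedSite:
    hairpin: str
    transcript_id: str
    start: int
    end: int
    penalty: float
    penalty_class: str  # "perfect" | "low" | "mid" | "above_cutoff"


@dataclass
class TruthSet:
    contigs: list[SequenceRecord] = field(default_factory=list)
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    contaminants: list[SequenceRecord] = field(default_factory=list)
    catalog: list[SequenceRecord] = field(default_factory=list)
    transcripts: list[SequenceRecord] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)

    def hairpin(self, name: str) -> PlantedHairpin:
        return next(h for h in self.hairpins if h.name == name)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_ACGT, size=n, p=p).tobytes().decode()


def _category_plan(n_hairpins: int) -> list[str]:
    """Deterministic category mix: ~1/4 known, ~1/5 variant, rest novel (3:1 true:candidate)."""
    n_known = max(1, round(0.25 * n_hairpins))
    n_variant = max(1, round(0.20 * n_hairpins)) if n_hairpins >= 4 else 0
    n_rest = n_hairpins - n_known - n_variant
    n_candidate = max(1, round(0.25 * n_rest)) if n_rest >= 2 else max(0, n_rest - 1)
    n_true = n_rest - n_candidate
    return (
        ["known"] * n_known
        + ["variant"] * n_variant
        + ["true_novel"] * n_true
        + ["candidate_novel"] * n_candidate
    )


def _default_multipliers(rng: np.random.Generator, idx: int) -> dict[str, float]:
    """Library-specific abundance multipliers for hairpin number ``idx``.

    Stress responses cycle through heat-induced (x4), salt-repressed (x0.25)
    and water-deficit-induced (x2); tissue presence patterns cycle through
    designs that populate every Venn region class.
    """
    mult = {lib: 1.0 for lib in ALL_LIBRARIES}
    stress_cycle = idx % 4
    if stress_cycle == 0:
        mult["HS"] = 4.0
    elif stress_cycle == 1:
        mult["SS"] = 0.25
    elif stress_cycle == 2:
        mult["WDS"] = 2.0
    tissue_patterns = [
        TISSUE_LIBRARIES,                      # all four
        ("shoot",),
        ("root",),
        ("mature_leaf", "shoot"),
        ("spikelet",),
        ("shoot", "root", "mature_leaf"),
        TISSUE_LIBRARIES,
        ("mature_leaf",),
    ]
    present = tissue_patterns[idx % len(tissue_patterns)]
    for lib in TISSUE_LIBRARIES:
        if lib not in present:
            mult[lib] = 0.0
    return mult


def _plant_one_hairpin(
    rng: np.random.Generator,
    contig_arr: bytearray,
    contig_id: str,
    contig_backup: bytes,
    pos: int,
    name: str,
    category: str,
    idx: int,
    max_tries: int = 60,
) -> PlantedHairpin | None:
    """Write one validated hairpin into the contig at ``pos``; None if exhausted.

    Validation folds the genuine 100-nt-flank precursor in its genomic
    context and requires the screen to accept it with the planted star
    recovered exactly, so downstream recovery is guaranteed by construction.
    """
    for _ in range(max_tries):
        mature_len = int(rng.choice([20, 21, 22], p=[0.15, 0.70, 0.15]))
        mature = to_rna(_random_seq(rng, mature_len))
        if is_low_complexity(mature):
            continue
        loop_len = int(rng.integers(8, 61))
        loop = to_rna(_random_seq(rng, loop_len))
        tail = to_rna(_random_seq(rng, 2))
        arm = revcomp_rna(mature[: mature_len - 2])
        n_mut = int(rng.integers(0, 3))
        arm_list = list(arm)
        if n_mut:
            sites = rng.choice(len(arm_list), size=n_mut, replace=False)
            for s in sites:
                choices = [b for b in "ACGU" if b != arm_list[s]]
                arm_list[s] = choices[int(rng.integers(0, 3))]
        core = mature + loop + "".join(arm_list) + tail
        star = core[mature_len + loop_len : mature_len + loop_len + mature_len]

        # paste into genomic context and validate in place
        core_dna = to_dna(core).encode()
        contig_arr[pos : pos + len(core_dna)] = core_dna
        contig_seq = contig_arr.decode()
        hit = GenomeHit(contig_id, pos, pos + mature_len, "+", to_dna(mature))
        prec = extract_precursor(hit, contig_seq)
        cand = evaluate_hairpin(prec, fold(prec.seq))
        ok = (
            cand.accepted
            and cand.duplex is not None
            and cand.duplex.star_seq == star
            and star != mature
            and contig_seq.count(to_dna(mature)) == 1
            and contig_seq.count(revcomp_dna(to_dna(mature))) == 0
        )
        if ok:
            star_ratio = 0.0 if category == "candidate_novel" else float(
                rng.uniform(0.1, 0.5)
            )
            weight = float(np.exp(rng.uniform(np.log(50), np.log(500))))
            return PlantedHairpin(
                name=name,
                contig=contig_id,
                mature_start=pos,
                mature=mature,
                star=star,
                loop_len=loop_len,
                arm_mutations=n_mut,
                category=category,
                star_ratio=star_ratio,
                weight=weight,
                multipliers=_default_multipliers(rng, idx),
            )
        contig_arr[pos : pos + len(core_dna)] = contig_backup[pos : pos + len(core_dna)]
    return None


def make_genome(
    n_contigs: int = 2,
    contig_len: int = 20000,
    n_hairpins: int = 20,
    seed: int = 0,
    gc: float = 0.45,
) -> tuple[list[SequenceRecord], TruthSet]:
    """Random background contigs with validated MIR hairpins embedded.

    Each hairpin is mature + loop (8-60 nt) + mutated reverse-complement arm
    (0-2 substitutions) + a 2-nt tail enforcing the canonical 2-nt 3'
    overhang register.  Placement is non-overlapping with a 250-nt margin;
    exhaustion raises.
    """
    if contig_len < 500:
        raise ValueError("contig_len must be at least 500")
    if n_hairpins < 1:
        raise ValueError("need at least one hairpin")
    rng = np.random.default_rng(seed)
    backgrounds = [_random_seq(rng, contig_len, gc) for _ in range(n_contigs)]
    arrays = [bytearray(b.encode()) for b in backgrounds]
    backups = [bytes(a) for a in arrays]
    ids = [f"contig_{i + 1}" for i in range(n_contigs)]

    margin = 250
    slot_span = 2 * 22 + 60 + margin  # worst-case hairpin footprint plus margin
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_contigs)}
    categories = _category_plan(n_hairpins)
    hairpins: list[PlantedHairpin] = []
    for idx, category in enumerate(categories):
        placed = None
        for _ in range(200):
            ci = int(rng.integers(0, n_contigs))
            pos = int(rng.integers(margin, contig_len - slot_span))
            if any(not (pos + slot_span <= a or pos >= b) for a, b in occupied[ci]):
                continue
            placed = (ci, pos)
            break
        if placed is None:
            raise RuntimeError("could not place hairpins without overlap (genome too small)")
        ci, pos = placed
        hp = _plant_one_hairpin(
            rng, arrays[ci], ids[ci], backups[ci], pos, f"hp_{idx + 1}", category, idx
        )
        if hp is None:
            raise RuntimeError(f"failed to construct a valid hairpin at slot {idx + 1}")
        occupied[ci].append((pos, pos + slot_span))
        hairpins.append(hp)

    contigs = [SequenceRecord(cid, arr.decode()) for cid, arr in zip(ids, arrays)]
    # contaminant inventory: t/rRNA-like reference sequences
    contaminants = [
        SequenceRecord(f"rRNA_{i + 1}", _random_seq(rng, 1200, gc=0.55)) for i in range(6)
    ] + [SequenceRecord(f"tRNA_{i + 1}", _random_seq(rng, 90, gc=0.55)) for i in range(4)]
    truth = TruthSet(contigs=contigs, hairpins=hairpins, contaminants=contaminants)
    return contigs, truth


def _windows_from(rng: np.random.Generator, pool: list[str], n: int) -> list[str]:
    """n random 16-30-nt windows from the pooled sequences, length-weighted."""
    out = []
    lens = rng.choice(_DEG_LENGTHS, size=n, p=_DEG_WEIGHTS)
    refs = rng.integers(0, len(pool), size=n)
    for length, ri in zip(lens, refs):
        ref = pool[int(ri)]
        start = int(rng.integers(0, max(1, len(ref) - int(length))))
        out.append(ref[start : start + int(length)])
    return out


def simulate_libraries(
    truth: TruthSet,
    libraries: tuple[str, ...] = ALL_LIBRARIES,
    depth: int = 200_000,
    proportions: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, list[str]], dict[str, dict[str, int]]]:
    """Draw per-library reads (DNA strings) from the planted truth.

    Returns (reads per library, per-library drawn category tallies).  Read
    classes and their stated proportions: planted matures (with per-library
    differential multipliers) and their stars (per star:mature ratio),
    contaminant windows, degradation windows from transcripts, out-of-range
    junk lengths, and N-containing invalid reads.
    """
    if depth < 10_000:
        raise ValueError("depth must be at least 10^4")
    props = dict(DEFAULT_PROPORTIONS if proportions is None else proportions)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError(f"category proportions sum to {sum(props.values())}, not 1")
    rng = np.random.default_rng(seed)
    cats = list(props)
    p = np.array([props[c] for c in cats])

    deg_pool = [to_dna(t.seq) for t in truth.transcripts]
    if not deg_pool:
        deg_pool = [_random_seq(rng, 800) for _ in range(10)]
    cont_pool = [to_dna(c.seq) for c in truth.contaminants]

    # library-independent normalisation of hairpin weights, so a x4 multiplier
    # yields a x4 expected read count (not renormalised away within the class)
    base_weight = sum(hp.weight * (1.0 + hp.star_ratio) for hp in truth.hairpins)

    libs: dict[str, list[str]] = {}
    tallies: dict[str, dict[str, int]] = {}
    for lib in libraries:
        reads: list[str] = []
        tallies[lib] = {}
        for cat, p_cat in zip(cats, p):
            if cat == "mirna":
                # per-entry Poisson draws against the base normalisation
                n_drawn = 0
                for hp in truth.hairpins:
                    m = hp.multipliers.get(lib, 1.0)
                    if m <= 0:
                        continue
                    lam_mature = depth * p_cat * hp.weight * m / base_weight
                    c = int(rng.poisson(lam_mature))
                    reads.extend([to_dna(hp.mature)] * c)
                    n_drawn += c
                    if hp.star_ratio > 0:
                        c = int(rng.poisson(lam_mature * hp.star_ratio))
                        reads.extend([to_dna(hp.star)] * c)
                        n_drawn += c
                tallies[lib][cat] = n_drawn
                continue
            n = int(rng.binomial(depth, p_cat))
            tallies[lib][cat] = n
            if n == 0:
                continue
            if cat == "contaminant":
                reads.extend(_windows_from(rng, cont_pool, n))
            elif cat == "degradation":
                reads.extend(_windows_from(rng, deg_pool, n))
            elif cat == "junk_length":
                lens = rng.choice(
                    list(range(10, 16)) + list(range(31, 41)), size=n
                )
                reads.extend(_random_seq(rng, int(l)) for l in lens)
            elif cat == "invalid":
                for _ in range(n):
                    s = list(_random_seq(rng, int(rng.integers(16, 31))))
                    for j in rng.choice(len(s), size=int(rng.integers(1, 3)), replace=False):
                        s[j] = "N"
                    reads.append("".join(s))
            else:
                raise ValueError(f"unknown read category {cat!r}")
        order = rng.permutation(len(reads))
        libs[lib] = [reads[i] for i in order]
    return libs, tallies


_SPECIES = ("osa", "zma", "bdi", "hvu", "ata", "tae")
_FAMILIES = (156, 160, 164, 166, 167, 171, 396, 1120, 1432, 5084)


def make_catalog(
    truth: TruthSet, seed: int = 0, n_decoys: int = 25
) -> list[SequenceRecord]:
    """miRBase-style mature catalog realising the designed category distances.

    Known hairpins get exact copies; variant hairpins get 1-2-substitution
    homologs; novel hairpins are omitted; decoy entries are random matures at
    least 3 mismatches from every planted mature.
    """
    rng = np.random.default_rng(seed)
    planted = [h.mature for h in truth.hairpins]

    def mm(a: str, b: str) -> int:
        if len(a) != len(b):
            return max(len(a), len(b))
        return sum(1 for x, y in zip(a, b) if x != y)

    def fresh_id(i: int, arm: bool = False) -> str:
        sp = _SPECIES[i % len(_SPECIES)]
        fam = _FAMILIES[i % len(_FAMILIES)]
        letter = "abcdefghij"[(i // len(_FAMILIES)) % 10]
        suffix = "-5p" if arm and i % 3 == 0 else ""
        return f"{sp}-miR{fam}{letter}{suffix}"

    entries: list[SequenceRecord] = []
    i = 0
    for hp in truth.hairpins:
        if hp.category == "known":
            entries.append(SequenceRecord(fresh_id(i, arm=True), hp.mature))
            i += 1
        elif hp.category == "variant":
            for _ in range(50):
                k = int(rng.integers(1, 3))
                seq = list(hp.mature)
                for s in rng.choice(len(seq), size=k, replace=False):
                    seq[s] = [b for b in "ACGU" if b != seq[s]][int(rng.integers(0, 3))]
                homolog = "".join(seq)
                others = [m for m in planted if m != hp.mature]
                if all(mm(homolog, m) >= 3 for m in others):
                    entries.append(SequenceRecord(fresh_id(i), homolog))
                    i += 1
                    break
            else:
                raise RuntimeError("could not derive a variant homolog")
    novel_matures = [
        h.mature for h in truth.hairpins if h.category in ("true_novel", "candidate_novel")
    ]
    for d in range(n_decoys):
        for _ in range(50):
            decoy = to_rna(_random_seq(rng, int(rng.choice([20, 21, 22]))))
            if all(mm(decoy, m) >= 3 for m in planted):
                entries.append(SequenceRecord(fresh_id(i), decoy))
                i += 1
                break
    # sanity: no novel planted mature may sit within the variant band of the catalog
    for m in novel_matures:
        if any(mm(m, e.seq) <= 2 for e in entries):
            raise RuntimeError("catalog decoy collided with a planted novel mature")
    truth.catalog = entries
    return entries


_SITE_CLASSES = ("perfect", "low", "mid", "above_cutoff")


def _edit_site(
    rng: np.random.Generator, mature: str, cls: str
) -> str:
    """Build a target site of the requested penalty class for ``mature``.

    Edits are placed at fixed miRNA positions: class 'low' puts one mismatch
    outside the core (expected penalty 1.0), 'mid' two non-core mismatches
    plus a non-core wobble-or-mismatch (2.5-3.0), 'above_cutoff' two core
    mismatches (4.0).
    """
    m = to_rna(mature)
    lm = len(m)
    site = list(revcomp_rna(m))  # perfect complement, site 5'->3'

    def set_state(pos: int, state: str) -> None:
        j = lm - pos  # site index facing miRNA position ``pos`` (1-based)
        base = m[pos - 1]
        if state == "mismatch":
            bad = {"A": "C", "C": "A", "G": "G", "U": "C"}[base]
            site[j] = bad
        elif state == "wobble":
            if base in "GU":
                site[j] = {"G": "U", "U": "G"}[base]
            else:  # A/C cannot wobble: fall back to a mismatch
                site[j] = {"A": "C", "C": "A"}[base]

    if cls == "low":
        set_state(lm - 1, "mismatch")
    elif cls == "mid":
        set_state(lm - 1, "mismatch")
        set_state(lm - 3, "mismatch")
        set_state(lm - 5, "wobble")
    elif cls == "above_cutoff":
        set_state(5, "mismatch")
        set_state(7, "mismatch")
    elif cls != "perfect":
        raise ValueError(f"unknown site class {cls!r}")
    return to_dna("".join(site))


def make_transcriptome(
    truth: TruthSet, n_transcripts: int = 30, seed: int = 0
) -> list[SequenceRecord]:
    """Random transcripts carrying planted target sites of designed penalty classes."""
    if n_transcripts < 1:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(seed)
    transcripts = [
        bytearray(_random_seq(rng, int(rng.integers(500, 1501))).encode())
        for _ in range(n_transcripts)
    ]
    ids = [f"TC{400000 + i}" for i in range(n_transcripts)]
    sites: list[PlantedSite] = []
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_transcripts)}
    targeted = [h for h in truth.hairpins][: max(4, len(truth.hairpins) // 2)]
    for k, hp in enumerate(targeted):
        cls = _SITE_CLASSES[k % len(_SITE_CLASSES)]
        site_dna = _edit_site(rng, hp.mature, cls)
        for _ in range(100):
            ti = int(rng.integers(0, n_transcripts))
            tr = transcripts[ti]
            start = int(rng.integers(50, len(tr) - len(site_dna) - 50))
            span = (start - 30, start + len(site_dna) + 30)
            if all(span[1] <= a or span[0] >= b for a, b in occupied[ti]):
                break
        else:
            raise RuntimeError("could not place target sites without overlap")
        occupied[ti].append(span)
        tr[start : start + len(site_dna)] = site_dna.encode()
        aln = score_site(hp.mature, to_rna(site_dna))
        sites.append(
            PlantedSite(
                hairpin=hp.name,
                transcript_id=ids[ti],
                start=start,
                end=start + len(site_dna),
                penalty=aln.penalty,
                penalty_class=cls,
            )
        )
    truth.transcripts = [
        SequenceRecord(tid, tr.decode()) for tid, tr in zip(ids, transcripts)
    ]
    truth.sites = sites
    return truth.transcripts
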