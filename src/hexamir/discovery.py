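"""Hairpin-based miRNA discovery.

Each exact genome hit seeds a candidate precursor (the mapped read plus
100-nt flanks).  The precursor is folded with a deterministic pairing-score
dynamic program (GC=+3, AU=+2, GU=+1, terminal loops of at least 3 unpaired
bases) and the candidate is screened with the community annotation rules for
plant miRNAs: mature and star on opposite arms of one stem-loop, canonical
2-nt 3' overhangs in the duplex, and at most 4 mismatches between mature and
star.  A thermodynamic folding engine (ViennaRNA) can be plugged in through
the same output contract; the internal DP is the default because it is
deterministic and oracle-testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._seq import gc_percent, is_wc_or_wobble, pair_score, revcomp_dna, to_rna
from .genome_map import GenomeHit

__all__ = [
    "Precursor",
    "FoldResult",
    "DuplexReport",
    "HairpinCandidate",
    "extract_precursor",
    "fold",
    "vienna_fold",
    "predict_star",
    "duplex_mismatches",
    "evaluate_hairpin",
    "precursor_stats",
    "discover_hairpins",
]

MIN_LOOP = 3
FLANK = 100
MAX_DUPLEX_MISMATCHES = 4
OVERHANG = 2


@dataclass
class Precursor:
    """Candidate precursor window with the mature read located inside it."""

    contig: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str
    seq: str  # RNA, 5'->3' in read orientation
    mature_offset: int
    mature_len: int

    @property
    def mature_seq(self) -> str:
        return self.seq[self.mature_offset : self.mature_offset + self.mature_len]


@dataclass
class FoldResult:
    """Nested secondary structure of a sequence.

    ``score`` is in pairing-score units (higher = more stable) for the
    internal engine, or kcal/mol free energy (lower = more stable) when a
    thermodynamic plug-in produced it (``engine`` records which).
    """

    seq: str
    structure: str
    score: float
    pair_table: list[int | None]
    engine: str = "score"


@dataclass
class DuplexReport:
    star_seq: str | None
    star_start: int | None  # within precursor
    star_end: int | None
    mismatches: int | None
    mature_overhang: int | None
    star_overhang: int | None
    opposite_arms: bool
    mature_unpaired: int


@dataclass
class HairpinCandidate:
    precursor: Precursor
    fold: FoldResult
    duplex: DuplexReport | None
    trimmed_start: int | None  # within precursor
    trimmed_end: int | None
    gc_content: float
    accepted: bool
    reject_reason: str | None = None
    read_counts: dict = field(default_factory=dict)

    @property
    def mature_seq(self) -> str:
        return self.precursor.mature_seq

    @property
    def trimmed_seq(self) -> str | None:
        if self.trimmed_start is None:
            return None
        return self.precursor.seq[self.trimmed_start : self.trimmed_end]


def extract_precursor(hit: GenomeHit, contig_seq: str, flank: int = FLANK) -> Precursor:
    """Cut the [start-flank, end+flank) window around a hit, clipped to the contig.

    Minus-strand hits are reverse-complemented so the mature reads 5'->3'
    within the returned precursor sequence.
    """
    n = len(contig_seq)
    ws = max(0, hit.start - flank)
    we = min(n, hit.end + flank)
    window = contig_seq[ws:we]
    if hit.strand == "+":
        seq = to_rna(window)
        offset = hit.start - ws
    else:
        seq = to_rna(revcomp_dna(window))
        offset = we - hit.end
    return Precursor(
        contig=hit.contig,
        start=ws,
        end=we,
        strand=hit.strand,
        seq=seq,
        mature_offset=offset,
        mature_len=hit.end - hit.start,
    )


def fold(seq: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Optimal nested structure under the pairing-score model.

    Maximises the sum of pair scores (GC=3, AU=2, GU=1) over all pseudoknot-
    free structures with hairpin loops of at least ``min_loop`` unpaired
    bases.  Tie-break: the traceback pairs the left-most base first, with its
    left-most admissible partner.
    """
    rna = to_rna(seq)
    n = len(rna)
    if any(c not in "ACGU" for c in rna):
        bad = next(c for c in rna if c not in "ACGU")
        raise ValueError(f"invalid character {bad!r} in sequence")
    if n == 0:
        return FoldResult(rna, "", 0.0, [])

    # pair-score matrix
    codes = np.frombuffer(rna.encode(), dtype=np.uint8)
    S = np.zeros((n, n), dtype=np.int64)
    score_of = {}
    for a in "ACGU":
        for b in "ACGU":
            score_of[(ord(a), ord(b))] = pair_score(a, b)
    for i in range(n):
        row = S[i]
        ai = codes[i]
        for j in range(i + min_loop + 1, n):
            row[j] = score_of[(ai, codes[j])]

    W = np.zeros((n + 1, n + 1), dtype=np.int64)  # W[i][j]: best over i..j inclusive
    for l in range(min_loop + 1, n):
        for i in range(0, n - l):
            j = i + l
            best = W[i + 1][j]
            ks = np.arange(i + min_loop + 1, j + 1)
            sc = S[i, ks]
            pairable = sc > 0
            if pairable.any():
                ksp = ks[pairable]
                cand = sc[pairable] + W[i + 1, ksp - 1] + W[ksp + 1, j]
                m = cand.max()
                if m > best:
                    best = m
            W[i][j] = best

    # traceback: prefer pairing the left-most base, left-most partner
    pair_table: list[int | None] = [None] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1 or W[i][j] == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            s = S[i][k]
            if s and s + W[i + 1][k - 1] + W[k + 1][j] == W[i][j]:
                pair_table[i] = k
                pair_table[k] = i
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    structure = "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(pair_table)
    )
    return FoldResult(rna, structure, float(W[0][n - 1]), pair_table, engine="score")


def vienna_fold(seq: str) -> FoldResult:
    """Thermodynamic plug-in honouring the FoldResult contract (requires ViennaRNA)."""
    import RNA  # optional dependency; ships with the ViennaRNA suite

    rna = to_rna(seq)
    structure, mfe = RNA.fold(rna)
    pair_table: list[int | None] = [None] * len(rna)
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pair_table[i], pair_table[j] = j, i
    return FoldResult(rna, structure, float(mfe), pair_table, engine="vienna")


def _register_mismatches(mature: str, star: str, shift: int) -> int:
    """Mismatches with ``mature`` as guide at duplex register ``shift``.

    The register pairs mature[i] with star[len(star)-1-shift-i]; shift = 2 is
    the canonical Dicer geometry (2-nt 3' overhang on each strand), shift = 0
    the blunt duplex.  Each duplex end grants a free allowance of 2
    overhanging bases; unaligned bases beyond it count one each.
    """
    m, s = to_rna(mature), to_rna(star)
    lm, ls = len(m), len(s)
    mm = 0
    for i in range(lm):
        j = ls - 1 - shift - i
        if 0 <= j < ls:
            if not is_wc_or_wobble(m[i], s[j]):
                mm += 1
    # end with mature 3' / star 5' overhangs
    end_a = max(0, lm - ls + shift) + max(0, ls - lm - shift)
    # end with mature 5' / star 3' overhangs
    end_b = max(0, -shift) + max(0, min(shift, ls))
    return mm + max(0, end_a - OVERHANG) + max(0, end_b - OVERHANG)


def duplex_mismatches(mature: str, star: str) -> int:
    """Mismatch count between a mature miRNA and its star strand.

    A position counts as a mismatch unless it forms a Watson-Crick or G:U
    pair; overhanging bases beyond a 2-nt allowance at each 3' end count one
    per base.  Because bulges in real hairpins shift the register in which a
    mature/star pair is reported, the minimum over nearby registers (and over
    both strand orderings, making the function symmetric) is returned; the
    canonical 2-nt-overhang Dicer register is always among those scanned.
    """
    for s in (mature, star):
        if not 19 <= len(s) <= 24:
            raise ValueError(f"duplex strand length {len(s)} outside 19-24 nt")
    return min(
        _register_mismatches(a, b, shift)
        for a, b in ((mature, star), (star, mature))
        for shift in range(-4, 5)
    )


def predict_star(fold_result: FoldResult, mature_span: tuple[int, int]):
    """Locate the star strand of the duplex in the canonical Dicer register.

    The star span covers the positions pairing with the mature, shifted so
    both 3' ends carry exactly 2 overhanging nucleotides.  Returns
    (star_seq, star_start, star_end, mature_overhang, star_overhang) or None
    when fewer than mature_length - 4 mature bases pair outside the mature,
    when partners straddle both sides, or when the register runs off the
    precursor.
    """
    s, e = mature_span
    pt = fold_result.pair_table
    n = len(pt)
    outside = [
        (i, pt[i]) for i in range(s, e) if pt[i] is not None and not (s <= pt[i] < e)
    ]
    down = [(i, p) for i, p in outside if p >= e]
    up = [(i, p) for i, p in outside if p < s]
    partners = down if len(down) >= len(up) else up  # majority arm; strays ~ unpaired
    if len(partners) < (e - s) - 4:
        return None
    # antiparallel pairing keeps i + partner(i) nearly constant; drop stray
    # pairs whose implied register is far from the median (fold tie artefacts)
    regs = sorted(i + p for i, p in partners)
    median_reg = regs[len(regs) // 2]
    partners = [(i, p) for i, p in partners if abs(i + p - median_reg) <= 4]
    if len(partners) < (e - s) - 4:
        return None
    i_min = min(i for i, _ in partners)
    j_cands = [i for i, _ in partners if i <= e - 3]
    if not j_cands:
        return None
    j_max = max(j_cands)
    start = pt[j_max] - ((e - 3) - j_max)
    end = pt[i_min] + (i_min - s) + 3
    if start < 0 or end > n or start >= end:
        return None
    star_seq = fold_result.seq[start:end]
    return star_seq, start, end, OVERHANG, OVERHANG


def evaluate_hairpin(precursor: Precursor, fold_result: FoldResult) -> HairpinCandidate:
    """Screen one candidate against the plant-miRNA annotation rules."""
    if len(fold_result.seq) != len(precursor.seq):
        raise ValueError("fold result does not match precursor length")
    s = precursor.mature_offset
    e = s + precursor.mature_len
    pt = fold_result.pair_table

    # partners on the minority arm are score-tie artefacts of the fold and are
    # treated as unpaired for the <=4-base allowance
    outside = [pt[i] for i in range(s, e) if pt[i] is not None and not (s <= pt[i] < e)]
    n_down = sum(1 for p in outside if p >= e)
    n_up = len(outside) - n_down
    on_arm = max(n_down, n_up)
    mature_unpaired = (e - s) - on_arm
    opposite_arms = on_arm >= (e - s) - 4

    def rejected(reason: str, duplex: DuplexReport | None) -> HairpinCandidate:
        return HairpinCandidate(
            precursor=precursor,
            fold=fold_result,
            duplex=duplex,
            trimmed_start=None,
            trimmed_end=None,
            gc_content=gc_percent(precursor.seq),
            accepted=False,
            reject_reason=reason,
        )

    base_report = DuplexReport(
        star_seq=None,
        star_start=None,
        star_end=None,
        mismatches=None,
        mature_overhang=None,
        star_overhang=None,
        opposite_arms=opposite_arms,
        mature_unpaired=mature_unpaired,
    )
    if not opposite_arms:
        return rejected("mature spans the terminal loop or is unpaired", base_report)
    if mature_unpaired > 4:
        return rejected("mature unpaired over more than 4 bases", base_report)

    star = predict_star(fold_result, (s, e))
    if star is None:
        return rejected("no star strand in the canonical register", base_report)
    star_seq, star_start, star_end, m_ov, s_ov = star
    try:
        mismatches = duplex_mismatches(precursor.mature_seq, star_seq)
    except ValueError:
        return rejected("star length outside the duplex range", base_report)
    duplex = DuplexReport(
        star_seq=star_seq,
        star_start=star_start,
        star_end=star_end,
        mismatches=mismatches,
        mature_overhang=m_ov,
        star_overhang=s_ov,
        opposite_arms=True,
        mature_unpaired=mature_unpaired,
    )

    # trim to the maximal unbranched stem-loop enclosing the duplex: extend
    # outward while enclosing pairs stack around it without side hairpins
    lo = min(s, star_start)
    hi = max(e, star_end)  # half-open
    while True:
        x = lo - 1
        while x >= 0 and (pt[x] is None or pt[x] < hi - 1):
            x -= 1
        if x < 0:
            break
        y = pt[x]
        side_branch = any(
            pt[u] is not None and x < pt[u] < lo for u in range(x + 1, lo)
        ) or any(pt[u] is not None and hi - 1 < pt[u] < y for u in range(hi, y))
        if side_branch:
            break
        lo, hi = x, y + 1
    trimmed_start, trimmed_end = lo, hi

    accepted = mismatches <= MAX_DUPLEX_MISMATCHES and m_ov == OVERHANG and s_ov == OVERHANG
    return HairpinCandidate(
        precursor=precursor,
        fold=fold_result,
        duplex=duplex,
        trimmed_start=trimmed_start,
        trimmed_end=trimmed_end,
        gc_content=gc_percent(
            precursor.seq[trimmed_start:trimmed_end] if accepted else precursor.seq
        ),
        accepted=accepted,
        reject_reason=None if accepted else f"{mismatches} duplex mismatches",
    )


def precursor_stats(candidates: Sequence[HairpinCandidate]) -> dict[str, float]:
    """Length and GC ranges over the trimmed precursors of accepted candidates."""
    accepted = [c for c in candidates if c.accepted]
    if not accepted:
        raise ValueError("no accepted candidates")
    lengths = [c.trimmed_end - c.trimmed_start for c in accepted]
    gcs = [c.gc_content for c in accepted]
    return {
        "n": len(accepted),
        "min_length": min(lengths),
        "max_length": max(lengths),
        "min_gc": min(gcs),
        "max_gc": max(gcs),
    }


def discover_hairpins(
    unique_reads,
    index,
    flank: int = FLANK,
    fold_engine: Callable[[str], FoldResult] = fold,
) -> list[HairpinCandidate]:
    """Map each unique read, fold every hit's precursor, screen the hairpins.

    All loci of a multi-mapping read are evaluated independently; every
    candidate (accepted or not) is returned for accounting.
    """
    candidates: list[HairpinCandidate] = []
    for read in unique_reads:
        for hit in index.lookup(read.seq):
            prec = extract_precursor(hit, index.contigs[hit.contig], flank=flank)
            cand = evaluate_hairpin(prec, fold_engine(prec.seq))
            cand.read_counts = dict(read.counts)
            candidates.append(cand)
    return candidates


def deduplicate_loci(candidates: Sequence[HairpinCandidate]) -> list[HairpinCandidate]:
    """Collapse accepted candidates whose precursor windows overlap on a contig.

    The mature and star reads of one hairpin both map and both pass the
    screen; the most abundant read at a locus is kept as the mature (ties by
    sequence), mirroring how sRNA workbenches call the guide strand.
    """
    accepted = sorted(
        (c for c in candidates if c.accepted),
        key=lambda c: (c.precursor.contig, c.precursor.start),
    )
    groups: list[list[HairpinCandidate]] = []
    for cand in accepted:
        if (
            groups
            and groups[-1][-1].precursor.contig == cand.precursor.contig
            and cand.precursor.start < max(g.precursor.end for g in groups[-1])
        ):
            groups[-1].append(cand)
        else:
            groups.append([cand])
    kept = []
    for group in groups:
        group.sort(key=lambda c: (-sum(c.read_counts.values()), c.mature_seq))
        kept.append(group[0])
    return kept
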