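"""Complementarity-based miRNA target prediction on a transcriptome.

Each transcript window is aligned antiparallel to the miRNA and scored with
an Allen-style expectation penalty: mismatch +1, G:U wobble +0.5, gap +2,
with every penalty doubled in the core region (miRNA positions 2-13 from
the 5' end).  Sites at or below the expectation cutoff (default 3.0) are
reported with a silencing-mode call — cleavage (C) when the central
positions 9-11 are perfectly paired or wobbled, translational repression (T)
otherwise — and, for cleavage sites, the transcript coordinate pair facing
miRNA positions 10/11 where slicing is expected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._seq import to_rna
from .formats_io import SequenceRecord

__all__ = [
    "SiteAlignment",
    "TargetHit",
    "score_site",
    "call_mode",
    "expected_cleavage",
    "scan_transcripts",
]

DEFAULT_CUTOFF = 3.0
CORE = range(2, 14)  # miRNA positions with doubled penalties, 1-based 2..13
CENTRAL = (9, 10, 11)
GAP_PENALTY = 2.0
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5


def _pairs(mi: str, t: str) -> str:
    """Pairing state of a miRNA base against the transcript base it faces."""
    duo = mi + t
    if duo in ("AU", "UA", "GC", "CG"):
        return "pair"
    if duo in ("GU", "UG"):
        return "wobble"
    return "mismatch"


@dataclass
class SiteAlignment:
    """Antiparallel miRNA/site alignment with per-miRNA-position states.

    ``states[i]`` describes miRNA position i+1 (5'->3'): 'pair', 'wobble',
    'mismatch' or 'gap' (the miRNA base is bulged out of the duplex).
    ``site_index[i]`` is the 0-based index within the site window facing that
    position, or None for a gap.  ``site_gap_after`` marks a bulged site base
    (gap on the miRNA side), recorded as the miRNA position it follows.
    """

    mirna: str
    site: str
    states: list[str]
    site_index: list[int | None]
    site_gap_after: int | None = None

    @property
    def penalty(self) -> float:
        total = 0.0
        for i, state in enumerate(self.states, start=1):
            if state == "pair":
                continue
            p = {"wobble": WOBBLE_PENALTY, "mismatch": MISMATCH_PENALTY, "gap": GAP_PENALTY}[state]
            total += 2 * p if i in CORE else p
        if self.site_gap_after is not None:
            pos = self.site_gap_after
            total += 2 * GAP_PENALTY if pos in CORE else GAP_PENALTY
        return total

    def rows(self) -> tuple[str, str, str]:
        """Printable triple: miRNA 5'->3', pairing row, site 3'->5'."""
        top, mid, bottom = [], [], []
        for i, state in enumerate(self.states):
            top.append(self.mirna[i])
            if state == "gap":
                mid.append(" ")
                bottom.append("-")
            else:
                mid.append({"pair": "|", "wobble": ":", "mismatch": " "}[state])
                bottom.append(self.site[self.site_index[i]])
        return "".join(top), "".join(mid), "".join(bottom)


def _align_ungapped(mirna: str, site: str) -> SiteAlignment:
    lm = len(mirna)
    states, idx = [], []
    for i in range(lm):  # miRNA position i+1 faces site index lm-1-i
        j = lm - 1 - i
        states.append(_pairs(mirna[i], site[j]))
        idx.append(j)
    return SiteAlignment(mirna, site, states, idx)


def _align_mirna_bulge(mirna: str, site: str, g: int) -> SiteAlignment:
    """miRNA base at 1-based position g is bulged (site one base shorter)."""
    lm, ls = len(mirna), len(site)
    states, idx = [], []
    for i in range(1, lm + 1):
        if i == g:
            states.append("gap")
            idx.append(None)
            continue
        rank = i if i < g else i - 1  # position among paired miRNA bases
        j = ls - rank
        states.append(_pairs(mirna[i - 1], site[j]))
        idx.append(j)
    return SiteAlignment(mirna, site, states, idx)


def _align_site_bulge(mirna: str, site: str, b: int) -> SiteAlignment:
    """Site base at 0-based index b is bulged (site one base longer than miRNA)."""
    lm, ls = len(mirna), len(site)
    states, idx = [], []
    for i in range(1, lm + 1):
        j = ls - 1 - (i - 1)  # naive antiparallel index
        if j <= b:
            j -= 1  # skip the bulged site base
        states.append(_pairs(mirna[i - 1], site[j]))
        idx.append(j)
    # the bulge sits after the miRNA position whose partner precedes it
    gap_after = ls - 1 - b
    return SiteAlignment(mirna, site, states, idx, site_gap_after=gap_after)


def score_site(mirna: str, site: str) -> SiteAlignment:
    """Best alignment (at most one gap) of a miRNA against a transcript window.

    The site is the transcript subsequence 5'->3'; the miRNA pairs with it
    antiparallel (miRNA 5' end against the site 3' end).  Site length must be
    within one base of the miRNA length.
    """
    m = to_rna(mirna)
    s = to_rna(site)
    lm, ls = len(m), len(s)
    if ls == lm:
        return _align_ungapped(m, s)
    if ls == lm - 1:
        return min(
            (_align_mirna_bulge(m, s, g) for g in range(1, lm + 1)),
            key=lambda a: a.penalty,
        )
    if ls == lm + 1:
        return min(
            (_align_site_bulge(m, s, b) for b in range(0, ls)),
            key=lambda a: a.penalty,
        )
    raise ValueError(f"site length {ls} incompatible with miRNA length {lm} (one gap allowed)")


def call_mode(alignment: SiteAlignment) -> str:
    """'T' when a mismatch or gap occupies any of miRNA positions 9-11, else 'C'."""
    for pos in CENTRAL:
        state = alignment.states[pos - 1]
        if state in ("mismatch", "gap"):
            return "T"
        if alignment.site_gap_after == pos:
            return "T"
    return "C"


def expected_cleavage(alignment: SiteAlignment, site_span: tuple[int, int]) -> tuple[int, int]:
    """1-based transcript positions facing miRNA positions 11 and 10.

    Cleavage is expected between the two returned coordinates.  Only defined
    for cleavage-mode alignments.
    """
    if call_mode(alignment) != "C":
        raise ValueError("cleavage coordinate undefined for translational-repression sites")
    start, _end = site_span
    j11 = alignment.site_index[10]  # miRNA position 11
    j10 = alignment.site_index[9]   # miRNA position 10
    return (start + j11 + 1, start + j10 + 1)


@dataclass
class TargetHit:
    mirna_name: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    penalty: float
    mode: str  # "C" or "T"
    cleavage: tuple[int, int] | None
    alignment: SiteAlignment


def scan_transcripts(
    mirna: str,
    transcriptome: Sequence[SequenceRecord],
    cutoff: float = DEFAULT_CUTOFF,
    mirna_name: str = "query",
    max_hits_per_transcript: int | None = None,
) -> list[TargetHit]:
    """All windows with expectation penalty <= cutoff, deterministically ordered.

    Windows of the miRNA length and one base shorter/longer (single-gap
    alignments) are scored; hits sort by (penalty, transcript id, position).
    """
    if not transcriptome:
        raise ValueError("transcriptome must be non-empty")
    m = to_rna(mirna)
    lm = len(m)
    hits: list[TargetHit] = []
    for rec in transcriptome:
        t = to_rna(rec.seq)
        n = len(t)
        per_transcript: list[TargetHit] = []
        for width in (lm, lm - 1, lm + 1):
            if width < 1 or width > n:
                continue
            for w in range(0, n - width + 1):
                aln = score_site(m, t[w : w + width])
                if aln.penalty <= cutoff:
                    mode = call_mode(aln)
                    cleav = (
                        expected_cleavage(aln, (w, w + width)) if mode == "C" else None
                    )
                    per_transcript.append(
                        TargetHit(
                            mirna_name=mirna_name,
                            transcript_id=rec.id,
                            start=w,
                            end=w + width,
                            penalty=aln.penalty,
                            mode=mode,
                            cleavage=cleav,
                            alignment=aln,
                        )
                    )
        if max_hits_per_transcript is not None:
            per_transcript.sort(key=lambda h: (h.penalty, h.start))
            per_transcript = per_transcript[:max_hits_per_transcript]
        hits.extend(per_transcript)
    hits.sort(key=lambda h: (h.penalty, h.transcript_id, h.start))
    return hits
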