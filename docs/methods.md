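# Methods

This note documents the models, parameter choices and numerical decisions
behind hexamir, and what the synthetic benchmark does and does not show.

## Elimination pipeline

Reads are assigned to exactly one category by a fixed first-match priority:
length (outside 16–30 nt) → low complexity → invalid characters → t/rRNA
match. The priority makes the per-category tallies well defined and
rerun-stable; reordering the cascade would redistribute reads that belong
to several categories at once (an N-containing homopolymer, say), but the
putative population is unchanged. Tallies are kept separately for
redundant reads and unique sequences, and the conservation identity
`putative = total − Σ eliminated` is asserted, not assumed.

Parameter choices:

- **Length bounds 16/30 nt** — the windows used by small-RNA workbenches;
  also the bounds of the read classes the generator plants.
- **Low complexity**: a single k-mer (k ≤ 3) whose occurrences cover
  ≥ 80% of the read. This is a declared operationalisation of the
  SSR/tandem-repeat filters of sRNA workbenches, whose exact rules are not
  published; it is brute-force verifiable and catches mono-, di- and
  trinucleotide repeats. Desk re-runs of public datasets under this rule
  will not reproduce a workbench's category tallies exactly.
- **Invalid**: any character outside {A,C,G,U} after RNA normalisation;
  empty reads are invalid.
- **Contaminants**: exact substring of a t/rRNA reference or its reverse
  complement. No alignment — deterministic and sufficient when reference
  sets are the contaminants actually spiked by the generator; against real
  Rfam-scale sets an aligner would find more.
- **Adapter trimming**: exact match of the adapter's first 8 bases
  (configurable); reads without the seed are rejected when an adapter is
  configured. Mismatch-tolerant trimming is out of scope; sequencing-error
  models are not simulated, so exact seeds lose nothing here.

## Exact mapping

A k-mer hash (k = 16, the minimum read length) with full-length
verification returns all occurrences of a read on both strands, reported
in forward-strand coordinates and checked in the tests against a naive
O(n·m) scan. Multi-mapping reads keep all loci; each locus seeds an
independent precursor candidate, since MIR genes are commonly multi-copy.

## Folding

The default folding engine maximises a pairing score (GC = 3, AU = 2,
G:U = 1) over pseudoknot-free structures with hairpin loops of at least 3
unpaired bases — a Nussinov-style recursion with a deterministic
traceback that pairs the left-most base first, with its left-most
admissible partner. The scoring is a declared stand-in for free-energy
minimisation: it ranks stable hairpins the same way for screening
purposes, is exactly reproducible, and is verified against structure
enumeration (≤ 14 nt) and an independently written right-anchored
recursion (16–25 nt). `vienna_fold` exposes ViennaRNA's thermodynamic
model through the same `FoldResult` contract for users who want kcal/mol
energies; the screen only consumes the pair table, so the engines are
interchangeable. No numeric stability threshold is applied — candidates
are ranked, not cut, on folding score, because the screening criteria
below are the decisive filter.

## Hairpin screen

A candidate precursor is the mapped read ± 100 nt (clipped at contig
edges; minus-strand hits are reverse-complemented so the mature reads
5′→3′). Acceptance requires:

1. mature and star on opposite arms of one stem-loop — partners of mature
   bases must lie on one side; pairs on the minority side are score-tie
   artefacts of the fold and are counted as unpaired;
2. at most 4 mature bases unpaired within the duplex;
3. a star strand recoverable in the canonical Dicer register: the
   positions pairing the mature, shifted so both 3′ ends carry exactly
   2 overhanging nucleotides. The register is reconstructed by positional
   arithmetic from the innermost and outermost paired mature bases
   (register-consistency filtered to ± 4 around the median of i +
   partner(i)), so substitutions near the duplex ends do not shift the
   predicted star;
4. at most 4 mature/star duplex mismatches, where G:U wobbles pair and
   bulges count one per base.

The duplex mismatch count is the minimum over nearby registers (shifts
−4…+4, both strand orderings, 2-nt free overhang allowance per duplex
end). The register scan is needed because reported mature/star pairs sit
in frames that drift with bulges; the canonical 2-nt-overhang register is
always among those scanned, and the minimum makes the count symmetric.
Pairs whose hairpins contain arm indels can exceed 4 under this ungapped
counting even though a gapped alignment would pass them — 10 of the 49
packaged true-novel pairs are of this kind. Gapped duplex alignment is a
known limitation, deliberately excluded to keep the screen deterministic
and enumerable.

The reported ("trimmed") precursor is the maximal unbranched stem-loop
enclosing the duplex: enclosing pairs are followed outward until a side
hairpin branches off. The ±100-nt window is only the search region.

When several accepted candidates overlap at one locus — the planted star
read also maps and folds — the most abundant read is kept as the mature
and the locus is reported once, matching how sRNA workbenches call the
guide strand. Screen acceptance is *nearly* monotone in star-arm mutation
count: the duplex metric itself is strictly monotone, but the pipeline
refolds each precursor, and a substitution occasionally destroys a
competing stem and restores the planted one; the tests bound such rescues
rather than forbidding them.

## Classification

Known = 0 mismatches to the best catalog entry; variant = 1–2; novel =
≥ 3 or no entry. The 1–2 band is forced by the two outer definitions.
Length-mismatched comparisons use the best ungapped offset alignment with
overhanging bases counting 1; indels are not considered. Star detection is
an exact-sequence lookup in the cleaned unique reads, count ≥ 1 in any
library. Names: true novels `tae_N` and candidates `tae_CN` in descending
total count (ties lexicographic); known miRNAs keep their catalog names;
families are derived by stripping species prefixes and letter/arm
suffixes (zma-miR156i-5p → MIR156). Conservation across species sets is
exact substring presence on either strand.

## Expression

TPM = count / (library putative population) × 10⁶, so TPM sums to 10⁶
per library over the full putative population. Fold changes are
log₂(treatment/control); a zero on either side yields an
`undefined_zero` flag rather than a pseudo-counted value, because
imputation would silently move miRNAs across the ≥ 2-fold selection
boundary (|log₂FC| ≥ 1, boundary inclusive). Venn membership uses raw
count > 0 by default (configurable); the partition property — region
counts sum to the number of detected miRNAs — is asserted. Clustering is
UPGMA (scipy average linkage) on the uncentered-Pearson distance; labels
are sorted lexicographically before linkage so tie-breaks are
deterministic, all-zero profiles are rejected by name, and the result is
checked against an O(n³) reference implementation. Dendrograms serialise
to Newick with leaf depths of half the merge height.

## Target prediction

Allen-style expectation penalties (mismatch +1, G:U +0.5, gap +2;
doubled at miRNA positions 2–13) with a reporting cutoff of 3.0 — the
established default of plant target-prediction servers; both are
configurable. At most one gap per alignment keeps window enumeration
exhaustive (widths L−1, L, L+1). Mode is called T (translational
repression) when a mismatch or gap occupies miRNA positions 9–11, else C
(cleavage), and cleavage sites report the transcript coordinates facing
positions 11 and 10 — slicing is expected between them. Accessibility/UPE
terms and degradome support are out of scope.

## Synthetic data

The generator emulates an eight-library design (shoot, root, mature leaf,
spikelet, control, heat, salt, water-deficit) with:

- random background contigs at 45% GC (wheat-like, configurable);
- planted hairpins: mature (20–22 nt, mode 21) + loop (8–60 nt) +
  reverse-complement arm with 0–2 substitutions + 2-nt tail enforcing the
  canonical overhang register. Each hairpin is validated *in its genomic
  context* at generation time — folded with the production engine and
  required to pass the screen with the planted star recovered exactly —
  so downstream recovery failures indicate pipeline regressions, not
  generator noise;
- read classes per library: planted matures (12%), their stars at a
  star:mature ratio in (0.1, 0.5] (0 for designed candidate novels),
  t/rRNA contaminant windows (25%), degradation windows from transcripts
  (53%), out-of-range junk lengths (5%), N-containing invalid reads (5%).
  Degradation is drawn from transcripts only: windows of the contaminant
  references would be re-classified as t/rRNA matches by construction and
  would double-count that category. The miRNA share is kept modest on
  purpose: TPM is compositional, and planted fold-change multipliers are
  only recoverable from normalised expression when miRNA reads do not
  dominate the putative population;
- per-hairpin abundance weights log-uniform in [50, 500], with per-library
  multipliers (heat ×4, salt ×0.25, water-deficit ×2, cycling across
  hairpins; tissue presence patterns cycling through Venn region classes).
  miRNA counts are drawn per entry as Poisson against a
  library-independent normalisation, so a ×4 multiplier means a ×4
  expected count — a multinomial within the class would renormalise the
  design away;
- a catalog with exact copies (known), 1–2-substitution homologs
  (variant, distance-validated against all other planted matures) and
  random decoys ≥ 3 mismatches from everything planted;
- transcripts carrying target sites of designed penalty classes
  (0 / ~1 / ~2.5–3 / 4, the last above the cutoff).

What passing the benchmark does **not** show: behaviour under sequencing
error, adapter variants, quality-score artefacts, hc-siRNA cluster
structure, genuine bulged precursors (the generator plants
substitution-only arm mutations), or catalog entries with indels. The
published discovery counts of the wheat study derive from ~60M reads
against an unpublished in-house genome compilation and are not
reproducible at desk scale; the benchmark instead verifies that the
implementation recovers a fully known truth under the study's design.

## Benchmark problem sizes

The seeded benchmark uses 20 planted hairpins in 2 × 20 kb contigs and
eight libraries of 2 × 10⁵ reads — large enough that every category,
Venn region class and fold-change design point is populated, and small
enough that the whole run completes in minutes on one CPU. Unit and
property tests use smaller worlds (4–8 hairpins, 10⁴–2 × 10⁴ reads).
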