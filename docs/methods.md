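# Methods

`gvcompare` reimplements the comparative-genomics workflow used to
characterize betabaculovirus (granulovirus) genomes: a circular
double-stranded DNA genome of roughly 100 kb and ~37% G+C, densely packed
with ATG-initiated ORFs on both strands, carrying AT-rich intergenic
repeat regions (putative replication origins) and classic baculovirus
early/late promoter motifs. This note records the models, conventions and
numerical choices behind each stage, what the synthetic-data generator
does and does not emulate, and the known accuracy limits.

## Coordinates and sequence handling

All coordinates are 1-based inclusive on the forward strand of the
circle; position 1 is, by convention, the first nucleotide of the anchor
gene's start codon (granulin for granuloviruses). Internally each feature
carries a 0-based forward span start and a length, so spans may wrap
through the origin; BED export converts to 0-based half-open only at the
boundary. Input is normalized to upper case over {A,C,G,T,N}; U is
rejected (DNA-only), and N is tolerated in sequences but excluded from
composition denominators. FASTA and GenBank parsing is delegated to
Biopython; the GenBank LOCUS topology field is honored.

## ORF annotation

Candidates are all *maximal* ORFs on both strands: the first in-frame ATG
after the preceding in-frame stop, through the next in-frame stop, with
the stop codon counted in the nucleotide length (so the default 150 nt
threshold corresponds to 49 aa + stop). On a circular genome the scan
runs over a tripled copy of the sequence, so every locus is seen with a
real upstream stop and wrap-around ORFs are found naturally; results are
deduplicated modulo the genome length and ORFs longer than the genome are
rejected as degenerate. Internal-ATG enumeration is available behind a
flag (`all_starts`).

"Minimal overlap" selection is a greedy rule: candidates are taken
longest-first (ties: smaller start, then '+' strand) and kept iff their
nucleotide overlap with every already-kept ORF is at most
`max_overlap_fraction` (default 0.5) of the shorter of the two. The cap
is deliberately permissive because real granulovirus annotations retain
adjacent overlaps above 100 bp between kilobase-scale genes. Selected
ORFs are numbered 1..n by the leftmost forward coordinate of their span
('−' strand ORFs are ordered by their left edge, not their ATG, matching
how published genome maps number genes along the circle). Anchoring
rotates (and reverse-complements, if the anchor lies on '−') the genome
so the anchor ATG is at nt 1 on '+'; proteins are invariant under this
transform. Sub-threshold ORFs with external evidence (homology) can be
forced in through a rescue list rather than by lowering the threshold.

Summary statistics: orientation counts, span-union coding fraction
(computed on a per-base bitmap, wrap-aware) and the adjacent-overlap list
over consecutive ORFs in anchored order including the circular last-first
pair.

## Protein homology and gene classes

Pairwise protein comparison is exact affine-gap dynamic programming
(Needleman–Wunsch / Smith–Waterman via Biopython's `PairwiseAligner`)
under BLOSUM62 with gap open 11 and extension 1. At viral-proteome scale
(~10^2 proteins of ~10^2 aa) the exact DP is fast, deterministic, and can
be verified against an independent oracle, which a heuristic database
search cannot. A raw-score threshold (default 50) replaces E-values;
percent identity counts identical columns over all aligned columns, gap
columns included in the denominator (the conservative convention;
match-columns-only is a flag).

Orthologs between two annotated genomes are reciprocal best hits (RBH) by
local alignment score, ties broken toward the smaller ORF id, yielding a
deterministic one-to-one map. Gene classes are assigned against reference
panels (`family|member` FASTA) in fixed priority order — core >
lepidopteran-shared > betabaculovirus-specific > other — with "unique"
for ORFs hitting nothing; the panels are also scored for per-family
presence/absence independently of the per-ORF labels.

## Gene parity and inversions

A parity plot places each ortholog pair at (rank in A, rank in B), ranks
being ordinal positions in the anchored annotations. Rank origins are
aligned at the anchor-gene ortholog when present in both genomes,
otherwise at the circular rotation minimizing the summed circular rank
displacement (smallest rotation on ties). The collinearity score is the
fraction of circularly consecutive pairs (by rank A) whose rank-B step is
+1 modulo n_B: 1.0 for conserved gene order, ≈ 1/(m−1) for random order.
Inverted segments are maximal runs of ≥ 3 consecutive pairs with strictly
decreasing rank B (3 suppresses singleton transpositions; configurable);
spans are reported in genome-A nucleotides, boundary genes inclusive.
Strand discordance is carried per pair but does not define an inversion
on its own.

## Repeat regions, palindromes, hairpins

Intergenic spacers are maximal ORF-free regions (wrap-aware), reported
with their flanking ORFs.

**Direct repeats.** Tandem arrays of an imperfect unit are found by
seed-and-extend: exact 8-mers recurring at distance p (the candidate unit
length, 15 ≤ p ≤ L/2 by default) anchor array growth copy-by-copy, each
full copy constrained to ≤ `max_mismatch_fraction` (default 0.2)
mismatches against the running column consensus. Because the grown array
can sit off-phase (any rotation of the unit is an equally valid slicing)
and terminal copies can absorb background, boundaries are then refined
iteratively: (i) both boundaries are re-derived jointly as the
maximum-scoring segment (Kadane, +1 match / −1.5 mismatch) of the match
profile against the periodically tiled consensus; (ii) outward
max-prefix walks (+1/−2) re-attach partial copies that a mismatch
cluster hid from the segment pass, and a whole flanking copy within the
per-copy bound is rescued outright; (iii) copies are re-sliced at the
refined phase, the consensus rebuilt from them, and the pass repeated to
a fixpoint (≤ 3 rounds). Full copies are counted from the refined span;
a remainder of ≥ 75% of the unit counts as a trimmed full copy, one of
≥ 35–40% flags a truncated copy, smaller remainders are boundary slop.
Overlapping reports collapse to the candidate with the most full copies
(this prefers the fundamental unit over its 2p/3p harmonics), then the
longer span, the smaller unit, the leftmost start.

*Accuracy.* On planted arrays (units 20–50 nt, 3–7 copies, AT-rich
background) both boundaries are recovered to ±5 nt in ≥ 95% of cases at
5–10% per-copy substitution, degrading to ~85% at 15%. The degradation is
statistical, not algorithmic: at 12–15% per-base substitution the chance
that an array edge carries a cluster of ≥ 3 substitutions in its outer
few bases is several percent per edge, and such an edge carries no signal
distinguishing it from background for any detector.

**Palindromes.** Imperfect inverted repeats are scanned over every
(center, loop ≤ 10) placement, arms extended outward while the mismatch
fraction stays within bounds and the outermost position pairs; overlapping
reports collapse to the highest net pairing (arm − mismatches) with
mirror-invariant tie-breaks, so results on the reverse complement are the
mirrored coordinates.

**Hairpins.** Secondary structure is maximum base-pair nested folding
(Nussinov dynamic programming) over Watson–Crick pairs only (DNA — no
G·U wobble), minimum hairpin loop 3 nt, no thermodynamic parameters; the
traceback prefers closing a pair over unpairing, which yields the most
contiguous stem deterministically.

**Classification.** A region is `hr_like` when its repeat unit is built
around a dominant palindrome: the doubled consensus (doubling makes the
test invariant to the arbitrary detection phase) must contain a
palindrome with net pairing ≥ max(23, 0.45 × unit length). The absolute
floor of 23 was calibrated on AT-rich random units, where chance
palindromes of net ~16–20 are common; it implies hr-style architecture
is only callable for units of roughly ≥ 40 bp, consistent with the
30 bp palindromes of real NPV hrs. Otherwise a region is `non_hr` when
it has ≥ 2 direct-repeat copies, region AT fraction ≥ 0.6 (measured on
the region itself, not a sliding window), and at least one palindrome or
a ≥ 4-pair hairpin within it; else `none`.

## Promoter motifs

Within a window (default 150 nt) upstream of each ORF's ATG on the coding
strand, wrap-aware: every TAAG is a late-promoter hit; an early hit is a
TATA box whose CAGT/CATT initiator starts 20–40 nt downstream of the TATA
end. Positions count nucleotides upstream of the ATG (1 = adjacent).
These motif definitions are the standard baculovirus conventions and are
fully configurable, since promoter classes in published genome tables are
rarely accompanied by explicit motif rules. The window may overlap an
upstream gene's coding sequence (these genomes are compact); a flag
restricts scanning to intergenic positions.

## Concatenated core-protein phylogeny

Per-gene protein alignments (supplied, or produced by the built-in
center-star aligner — approximate, adequate for closely related,
indel-poor families) are concatenated into a supermatrix; missing taxa
are gap-filled per block and masked. Pairwise distances are
Poisson-corrected, d = −ln(1 − p), with p the mismatch proportion over
mutually non-gap columns (pairwise deletion; complete deletion by flag)
and saturated pairs capped at 10. Trees are canonical neighbor joining
(Saitou–Nei Q criterion, deterministic lowest-index tie-break); negative
branch lengths are clamped to zero with the deficit moved to the sibling
edge, preserving the joined pair's path length. NJ is exact on additive
matrices, which the test suite exploits as a closed-form oracle. Support
is nonparametric bootstrap over columns: resample, rebuild
distance + NJ, and report the percentage of replicates containing each
internal bipartition of the point tree; deterministic given the seed.
Distance + NJ stands in for maximum likelihood deliberately — it is
deterministic and oracle-testable and suffices for topology-level
statements; the supermatrix exports to relaxed PHYLIP for external ML
tools. Near-saturated distances (p ≳ 0.9) inflate variance under the log
correction and can distort joins; keep comparisons within the family.

## The synthetic-data generator

`synthetic_data` emits circular genomes whose planted truth is exactly
recoverable by the annotation rules above:

* Background is i.i.d. at the target G+C (default 0.378). Planted ORFs
  are ATG + stop-free sense codons + stop, lengths 300–1200 nt by
  default, both strands, the anchor ORF fixed at nt 1 on '+'. Rejecting
  stop codons (which are A/T-rich) biases coding sequence slightly G+C
  rich, so densely coding genomes realize up to ~1 point above the
  target.
* Every planted ATG carries an immediately-upstream in-frame stop codon
  ("guard"), so the first-ATG-after-stop convention recovers planted
  starts exactly.
* Planted overlaps are tail-to-tail between a '+' ORF and the following
  '−' ORF, a multiple of 3 long (6–21 nt), with the shared bases
  engineered so both frames are stop-free and both stop codons lie inside
  the shared region. This is the one overlap geometry in which both
  planted proteins stay exact without rejection-sampling the upstream
  context; head-to-head and same-strand overlaps are not planted.
* Promoter motifs (TAAG, or TATA + 20–40 nt + CAGT/CATT) are written
  into the spacer upstream of chosen ORFs; repeat regions overwrite a
  designated spacer with n copies of an AT-rich unit mutated at a given
  rate, plus an optional truncated half-copy and an optional adjacent or
  unit-centered palindrome. Repeat units are rejection-sampled to contain
  a stop codon in all six tandem reading frames, so an array can never
  host a spurious ORF above threshold.
* After assembly, background ORFs ≥ 150 nt that were not planted are
  disrupted (an early in-frame stop, or a start-codon edit, at positions
  no planted feature covers) in a bounded fixpoint loop. Offenders buried
  entirely inside planted features cannot be edited; they are recorded in
  the truth table and are harmless in practice, since the overlap cap
  rejects fully nested candidates at selection time.
* Descendants are derived by codon-aware substitution: with probability
  equal to the target amino-acid divergence, a codon's residue is
  replaced by a different one (random sense codon), so planted proteins
  never gain stops and expected protein identity is 1 − divergence.
  Start/stop codons and bases shared between overlapping ORFs stay
  fixed. Inversion blocks (runs of consecutive ORF ranks) are
  reverse-complemented spacer-midpoint to spacer-midpoint, widening over
  planted overlaps at the boundaries; truth coordinates, strands and
  feature positions are remapped.

What the generator does **not** emulate: insertions/deletions,
recombination, gene gain/loss, codon-usage structure beyond G+C,
transcription signals beyond the two motif classes, and homologous-region
(hr) networks. Passing the end-to-end tests therefore demonstrates that
the pipeline recovers what it models — coordinates, orthology, gene
order, repeat architecture, motifs — not that it is robust to indel-rich
or recombining real data.

The fixed documentation/CI family (`fixture_family()`) is an ancestor of
30 ORFs over 30 kb (5 planted promoters, one 7-copy non-hr style repeat
with palindrome, seed 1234) plus two descendants at 20% amino-acid
divergence, one carrying a 12-gene inversion. Default simulated genomes
go up to ~120 kb / 130 ORFs; the tests use the 30 kb scale to keep the
whole suite fast.

## Pipeline

`run_pipeline` executes genome → annotate → (classify) → promoters →
repeats → (parity per comparator) → (phylogeny, ≥ 3 genomes) from one
declarative YAML/JSON configuration; any stage failure aborts with a
stage-named error, skipped stages are recorded in the manifest, and the
manifest carries version, config echo, input checksums, per-stage wall
time and the output inventory. Reports are byte-identical across reruns
with the same config and seeds. Exit codes: 0 success, 2 configuration
error, 3 stage failure.

## Known limitations

* Repeat-boundary localization degrades above ~12% per-copy mismatch
  (see above); copy counts inherit ±1 uncertainty when boundaries err by
  most of a unit.
* hr-like architecture is not callable for units much below 40 bp.
* The center-star aligner is a 2-approximation; for distant taxa supply
  external alignments.
* Bootstrap support on very short or near-saturated supermatrices is
  unstable, as with any distance bootstrap.
* The ORF caller models single-exon, ATG-initiated genes only — no
  splicing, frameshifts or non-ATG starts.
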