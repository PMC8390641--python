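# Methods

## The junction-local model

The package treats alternative TP53 isoform expression as a local splice
choice rather than a transcript-abundance problem.  For each alternative
splice event there is a set of *distinct* junctions (present only in
alternative isoforms) and a *competing main* junction (the direct splice of
the same flanking exons in NM_000546.6).  The exonic fraction
`D̄ / (M + D̄)` is then a percent-spliced-in-style statistic: under the
idealized assumption that every junction of a transcript is covered at a
rate proportional to that transcript's molar abundance, the fraction
estimates the molar proportion of the alternative splice form at that locus.
No expectation–maximization or full-isoform deconvolution is attempted —
at the sub-5% abundances involved, junction-spanning reads are the only
unambiguous evidence, and the statistic deliberately uses nothing else.

Assumptions worth keeping in mind:

* Coverage is locally uniform.  Real RNA-seq has positional and GC biases;
  the ratio is robust to any bias shared by the distinct and main junctions
  (they are within a few kb of each other) but not to junction-specific bias
  such as alignability differences.
* Each read is independent evidence.  Mates of a pair are counted
  independently, and no fragment-level deduplication is performed; duplicate
  -flagged reads are counted by default because cohort BAMs are consumed as
  provided.  Both choices are exposed as parameters.
* The two C-terminal distinct junctions measure the same splice event, so
  their counts are averaged (arithmetic mean, kept real-valued) rather than
  summed — summation would double-weight the alternative isoform relative to
  the single competing main junction.

## The junction-read rule

A read supports a junction only when (a) a skipped-region (CIGAR `N`)
boundary matches the annotated donor/acceptor exactly, (b) the blocks
adjacent to that skip carry at least `min_flank = 10` aligned bases each,
(c) the record has zero mismatches, and (d) at most half of the stored
sequence is soft-clipped.  Operationalization details that the rule text
leaves open, resolved here as package policy:

* "Zero mismatches" means aligner edit distance (NM tag) 0 **and** no
  insertion/deletion CIGAR operators.  Soft-clipped bases are not
  mismatches.  A record without an NM tag cannot prove zero mismatches: the
  default (`strict`) policy rejects it; a `permissive` policy falls back to
  the MD tag when present.
* The soft-clip budget uses the stored sequence length as denominator
  (hard-clipped bases are absent from the record and do not enter), and the
  boundary is inclusive: exactly half the read soft-clipped still passes.
* Flank support is counted within the single block adjacent to the skip,
  not accumulated across further skips — "both sides of the breakpoint" is
  read as contiguous support.
* A read with several skips is matched against the catalog once per skip; it
  may support several junctions but never the same junction twice, and an
  unmatched extra skip does not disqualify the read.
* Reject reasons are assigned in a fixed order (no_splice →
  breakpoint_mismatch → excess_softclip → has_indel/has_mismatch →
  short_flank) so audit trails are deterministic.

Secondary and supplementary alignments are excluded by default; unmapped
records are never evaluated.

## Junction catalog

Junction identity is genomic — `(chrom, donor_end, acceptor_start)` with
`donor_end` the last base of the upstream-in-genome exon — because spliced
aligners report skip boundaries in genome coordinates regardless of strand.
Strand affects only per-transcript exon numbering.  One consequence on the
minus strand (the TP53 situation): the 3-bp 5'UTR acceptor shift of
NM_001126112.2 appears on the `donor_end` side of the genomic junction, not
the `acceptor_start` side, and the catalog derivation accepts the shift on
either boundary.

Non-main junctions are classified by transcript role: the two junctions
shared by *all* beta-family (`cterm`) transcripts form the averaged pair;
the unique junction of the `utr5` transcript differing from a main junction
by exactly 3 bases on one boundary is the 5'UTR distinct junction;
junctions found only in `gamma` transcripts are `gamma_distinct` (countable
but excluded from default fraction outputs, since gamma-supporting reads
are vanishingly rare in real cohorts); anything else — e.g. the alternative
5' starts that Δ40/Δ133/Δ160 isoforms share across beta and gamma families —
is `other_distinct`.  The bundled TP53 model mirrors the public GRCh38
annotation for the ten accessions and lives in a data file
(`data/tp53_model.json`) so users can swap annotation releases; the exact
coordinates of the intron-9 alternative exons and the Δ133/Δ160 first exons
vary between annotation sources and should be reviewed before use against
real alignments.

## TP53 status and cohorts

WT requires *no* mutation call, log₂ CN-ratio > −0.9 and RSEM-normalized
expression > 300 — both strict inequalities, applied only to the WT
definition (mutant groups are defined by mutation class alone).  Samples
carrying both missense and truncating calls go to the truncating group with
a `mixed_classes_policy` flag: truncation dominates the transcript phenotype
being measured, and the flag enables sensitivity analyses that exclude such
samples.  Unmutated samples failing a gate are `excluded`, with the first
failing criterion (missing data → low CN → low expression) as the reason.
Normal-tissue samples are never status-classified; they participate only in
paired analyses.  Per-stratum contrasts are emitted only when both groups
have at least `min_group_size = 5` members.

## Statistics

Unpaired comparisons are two-tailed Welch (unequal-variance) t-tests;
paired comparisons are one-sample t-tests on within-pair differences, with
pairwise deletion of incomplete pairs.  Degenerate inputs get limiting
conventions, logged: both groups constant and equal → p = 1; constant and
different → p = 0.  The familywise level is `family_alpha / m`, with `m`
the number of tests actually executed (per-class truncating subtests count
individually); a fixed-`m` override lets users mirror an externally defined
test family.  Significance uses `p ≤ adjusted_alpha` (boundary inclusive).
Missing fractions are dropped per test.  No FDR-style alternatives are
offered in this version.

## Synthetic data

The generators exist so every stage can be exercised offline with known
truth; they emulate the statistical structure of real cohorts, not their
biology.

* **Toy locus** — an 11-exon plus-strand main transcript (a minus-strand
  variant exists for strand-invariance tests), a beta-like alternative
  inserting one 137-bp exon into the long intron between exons 9 and 10, a
  gamma-like alternative with a different inserted exon, and a 5'UTR
  alternative whose exon-2 acceptor is shifted by exactly 3 bases.  The
  sequence is random with no splice-motif realism; the rule never consults
  sequence.
* **Read simulator** — single-end reads (mates are counted independently
  anyway), uniform start positions along the source transcript, default
  read length 76 nt (the middle of the 48–101 nt range of the emulated
  cohorts), default mixture 93% main / 4% C-terminal / 2% 5'UTR / 1% gamma,
  matching the upper range of normal-tissue fractions.  Contamination
  knobs: soft-clip (terminal aligned bases converted to clips, so clip
  length and flank support interact realistically), single-base mismatches
  reflected in the NM tag, and one-base splice-boundary offsets.  Base
  qualities are constant.  The truth table records each read's final block
  list and the junctions it crossed at generation time; qualification flags
  are computed by a literal restatement of the rule on those block lists,
  fully independent of the CIGAR-parsing path it validates.
* **Cohort simulator** — per-sample counts drawn binomially at depth 5000
  (a junction coverage achievable by deep cohorts; acceptance checks use
  10,000) around group-true fractions: baseline 0.01 (tumor-cohort scale),
  +0.02 for the truncating group by default, mirroring the magnitude of
  aberrant-splicing effects in truncating-mutant tumors; missense sits at
  baseline, encoding the central negative finding that missense/WT groups do
  not differ.  Annotations are constructed so classification reproduces the
  intended labels exactly, with truncating samples cycling through the three
  classes so per-class subtests are populated.

What passing tests on these generators shows: the counting rule is
implemented exactly (oracle equivalence is bitwise on verdicts), the
estimator is calibrated under binomial sampling, and the testing layer
controls familywise error.  What it does not show: robustness to alignment
artifacts, reference bias, degraded RNA, or annotation mismatches in real
BAMs.

## Numerical and engineering choices

* Coordinates are 1-based inclusive internally (SAM/GFF convention).
* Catalog derivation is order-independent; junctions are stored once with
  the union of originating transcripts.
* Fractions with zero denominators propagate as NaN in tables and empty
  fields in TSV, and are excluded from summaries and tests (0/0 → 0 would
  bias medians downward in shallow samples).
* Welch/paired p-values come from the t distribution with
  Welch–Satterthwaite / n−1 degrees of freedom (scipy); unit tests pin them
  to an independently written closed-form computation at 1e-10.
* All generators take explicit seeds and are reproducible bit-for-bit; the
  pipeline writes a manifest with a configuration hash and input checksums,
  and identical inputs yield byte-identical stage tables.
* Problem sizes in the test and acceptance layers (10,000-read fixtures,
  500-replicate calibration runs, reduced-size null simulations) were chosen
  to make Monte-Carlo error small relative to the tested tolerances while
  keeping the suites quick on a single CPU.

## Known limitations

* Single-locus scope; no multi-gene catalogs, no liftover.
* No realignment or mismatch rescue: reads a spliced aligner soft-clipped
  across a junction are simply rejected, which can undercount junctions in
  low-quality data (conservative for both distinct and main counts).
* The N-terminal isoform family has no unique junctions and is therefore
  invisible to this analysis by construction.
* Whether original cohort analyses excluded duplicate or multi-mapped reads
  is not documented; defaults here count duplicates and primary alignments
  only, and flags expose the alternatives.
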