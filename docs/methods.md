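# Methods

This note documents the models, rules and numerical choices behind
`somapipe`, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the underlying procedure left room.

## Coordinates and primitives

All internal coordinates are 0-based half-open; conversion to 1-based happens
only in GTF (and would-be VCF) I/O. Interval arithmetic (padding,
intersection, merged total length, reciprocal overlap
`min(|a∩b|/|a|, |a∩b|/|b|)`) is implemented directly on sorted half-open
spans.

**Local alignment.** The aligner is gap-free seed-and-extend: exact
`min_seed`-mers select diagonals, and on each seeded diagonal the single
maximal-scoring segment under match +1 / mismatch −1 is taken (Kadane scan,
leftmost on ties). Identity is `matches / aligned_length` with
`aligned_length = matches + mismatches`. With `min_seed = 1` every diagonal
is scanned, so the top score provably equals the exhaustive gap-free
Smith–Waterman optimum; this is property-tested against a dynamic-programming
oracle on random instances up to 200 bp. Gaps are deliberately unsupported:
every downstream rule (perfect-match read support, 100%-identity repeats,
> 99%-identity overhangs, ≤ 1-mismatch contig confirmation) is stated in
terms of contiguous matching bases. A separate exact-run scan
(`exact_match_runs`) reports maximal 100%-identity runs, which the
misalignment rule needs because a maximal-scoring segment may absorb
flanking mismatches and dilute identity below 1.0.

**DUST.** The low-complexity score is the overlapping-trinucleotide
statistic `100 · Σ_t c_t(c_t−1)/2 / (n(n−1)/2)` over ACGT triplets
(N-containing triplets ignored). Published DUST variants differ in scale;
this normalization is fraction-of-maximum, so a homopolymer scores 100, a
perfect dinucleotide repeat ≈ 49, and the removal threshold of 60
(configurable) flags only strongly repetitive windows. Consequence worth
knowing: pure AT microsatellites fall below 60 on this scale.

**k-mers.** `kmerize` uses `k = round(fraction · read_length)` with Python's
round-half-to-even, clamped to ≥ 3. A 100 bp read at fraction 0.85 gives
k = 85 (16 k-mers); a 50 bp read gives k = 42, since 0.85 · 50 = 42.5 rounds
to even.

## Filter cascades

Thresholds are module constants equal to the clinical defaults (listed in
the README); the choices that needed interpretation:

- A missing caller metric skips its rule rather than failing it — a record
  is excluded only on evidence actually present.
- "Germline ref depth ≤ 50 and tumor VAF < 0.01" is one conjunctive rule
  (two independent rules would discard nearly all low-VAF calls regardless
  of germline coverage, which contradicts the separate 1% panel-of-normals
  rule existing at all).
- The control-cohort VAF rule is represented as a panel-of-normals frequency
  table input; the original control-set composition is not reproduced.
- "Excessively high mapping depth" is quantified as > 3× the chromosome
  average (configurable); no exact multiple is standard.
- Reporting thresholds are inclusive (VAF ≥ 5% / ≥ 10%).
- Splice-prediction aggregation: disruptive iff ≥ 3 programs each score
  > 30%, or the scores of **all** programs sum to ≥ 100% (restricting the sum
  to three contributing programs would make the two branches nearly
  redundant).
- Trio subtraction identifies variants by (chrom, pos, ref, alt); variants
  in exactly one comparison are labelled maternally/paternally inherited and
  excluded.

## TMB

Panel TMB divides the count of kept variants with VAF ≥ 0.10 intersecting
the padded exonic targets by the fixed panel size 3.012823 Mb, giving a
resolution of ≈ 0.33 mutations/Mb per on-target variant; indels count
toward the panel TMB by default (configurable), since the defining count is
"variants". WGS TMB divides by 2,897.310462 Mb; structural variant burden is
reported as a raw count with "high" above 200. Hypermutation bands are
half-open ([0,5), [5,10), [10,100), [100,∞)) to remove the printed-range gap
at 99.9/100, and actionability is TMB ≥ 5. Concordance stratifies pairs by
panel TMB into < 5, 5–10, > 10 and reports mean absolute and signed
(panel − WGS) differences plus band occupancy.

## Fusion validation

A candidate enters as a breakpoint pair (chrom, position, strand, gene); the
chimera is up to 200 strand-aware bases of transcript-order sequence on each
side, truncated at contig ends, with the junction index recorded.

- **Prefilters**: partners with miRNA/snoRNA/rRNA biotypes or on the
  mitochondrial contig are removed; read-throughs are same-chromosome,
  same-strand pairs whose 3′ partner is the 5′ gene's nearest downstream
  neighbor.
- **Normal panel**: a normal read supports a chimera only with a perfect
  match of ≥ 10 overlapping bases **spanning the junction** — without the
  spanning requirement any flank-only 10-mer (present verbatim in the
  genome) would remove every candidate. Removal needs > 3 supporting reads
  from > 3 samples (both strict).
- **Contig confirmation**: a simple de Bruijn assembler (k-ladder, k-mer
  multiplicity ≥ 2, maximal non-branching unitigs at least one read long,
  deterministic order) replaces an external assembler; a contig validates if
  it aligns across the junction with ≥ 3 bases on *each* side (the stricter
  reading of "3 bp of overlap") and ≤ 1 mismatch overall.
- **Gap filling**: the 5-base artificial gap removes chimera bases
  [junction−2, junction+3) — the procedure names no offset, so the gap is
  centred with the extra base 3′ (configurable). Read k-mers (85% of read
  length) anchored on a 12-base edge context vote one base at a time; a base
  is accepted at ≥ 2 covering k-mers. The left- and right-extended edges are
  merged at their maximal exact overlap; with extensions ℓ and r and overlap
  o, the rebuilt gap has length ℓ + r − o, and the candidate validates when
  ℓ ≥ 3, r ≥ 3 and |rebuilt − 5| ≤ 1. A single internal aligner replaces the
  original short-read/long-read dispatch at 50 bp; the perfect-match
  semantics are unchanged.
- **Genomic artifacts**: misalignment iff the chimera (either orientation)
  has a > 50-base run at 100% identity to a locus outside its own source
  flanks; low-complexity iff any 64-base window exceeds the DUST threshold;
  breakpoint artifact iff a genomic alignment at > 99% identity crosses the
  junction with more than 10 bases of overhang on the far side — for a true
  fusion the flank alignments end exactly at the junction, so any long
  high-identity read-through implies genomic contiguity.
- **Scoring** is an additive ordinal (not probabilistic), configurable:
  both breakpoints in CDS +2, both at splice junctions +2, GT–AG +2 /
  GC–AG·AT–AC +1, in frame +2, −3 per artifact flag. Frame uses phase
  arithmetic: in frame iff the 5′ segment's cumulative coding bases and the
  3′ breakpoint's coding offset agree modulo 3.

A candidate is **validated** iff it survives the prefilters and normal
panel, both breakpoint reconstructions succeed, and neither misalignment nor
breakpoint-artifact flags fire (the low-complexity flag is annotative, as in
the original review workflow).

## CNV actionability

The printed loss band "> −1.0" is read as "< −1.0"; otherwise losses would
overlap normal and gain bands. Classification (0 ± 0.2 / > 0.5 / < −1.0) and
the actionability thresholds (−2.0, −0.85, 0.85, 2.3) are kept as two
distinct layers, mirroring the two review tracks they come from. The
decision-tree order is artifact filter → classification → focality →
category thresholds → second hits → LOH. Copies are
`(2·2^log2 − 2(1−purity))/purity` with purity defaulting to 1. Second-hit
pairing accepts gene-annotated deletions, deletions containing the variant
position, and unannotated whole-chromosome losses. Visual IGV review is
replaced by the machine-readable per-event evidence table.

## Evolution

The "20%" expansion/contraction thresholds are absolute VAF points
(> 0.20 increase, ≥ 0.20 decrease), not relative changes — relative changes
would label a 1% → 1.3% drift an expansion. A driver is "absent" only when
its VAF is < 0.01 at ≥ 50× locus depth; shallower loci are unassessable and
cannot generate lost-driver calls. Detection (> 0.10), sharing (> 0.05) and
the linear threshold (> 0.75 of initial detected SNVs shared) are strict
inequalities. Same-day anatomically distinct samples are each compared
against the initial sample.

## Cohort statistics

Signature attribution is supervised non-negative least squares against a
fixed 96-channel catalog, rescaled to mutation counts — a deliberate
replacement for de novo NMF extraction, which needs hundreds of genomes and
is not desk-reproducible; the quantity consumed downstream (attributed SBS3
mutations, positive at ≥ 100) is preserved. Fisher tests are two-sided under
the minimum-likelihood convention (sum of all table probabilities ≤ the
observed one), delegated to `scipy.stats.fisher_exact` and property-tested
against exhaustive enumeration; zero-margin tables return p = 1 with a
warning. No multiple-testing correction is applied across the pairwise
tests, matching the source analysis. HR subset assignment gives germline
precedence when both germline and somatic HR variants exist. Clinical-utility
tallies count a participant once in "any utility" however many categories
they hit, with somatic categories on the somatic-analysis denominator.

## Synthetic cohorts

Generators draw from per-stage RNG streams seeded by (cohort seed, stage
tag), so stages regenerate independently and byte-identically. Study
conditions follow the cohort structure the statistics target: HR group sizes
25 / 26 / 242 with SBS3-activity probabilities 0.48 / 0.308 / 0.231; an
external reference of 2,780 samples at 13.3% enters enrichment analyses as
fixed counts. The default reference is a 60 kb genome with 12 multi-exon
genes (GT..AG introns, both strands, one each of miRNA/snoRNA/rRNA) plus a
2 kb mitochondrial contig — big enough to exercise every rule, small enough
that the full suite runs in about a minute. Fusion read sets plant 10 true
fusions, 5 recurrent artifacts (≥ 4 perfect junction reads in ≥ 4 of 8
normal samples), 2 read-throughs, 1 duplicated-region decoy (60 exact bases
copied to an intergenic locus) and 2 excluded-biotype candidates, at 20×
coverage with substitution-only errors (default 0). The clone tree gives
each of six clones 12 drivers and 4 passengers across two timepoints chosen
to realize all five driver-change categories, plus a flat-profile TMB = 0
decoy sample. TMB pairs place variants uniformly on a virtual genome of the
interrogatable size with 1,000 regularly spaced panel intervals totalling
the panel footprint. The signature catalog is synthetic: five
well-separated, block-concentrated profiles rather than real COSMIC shapes.

What passing tests therefore show — and do not. They show the rule set is
implemented exactly (boundaries, intersections, reconstructions) and that
each stage recovers planted truth in its intended regime. They do not show
performance on real data: real SBS3 is near-flat and much harder to refit
than the synthetic catalog; real sequencing has indel errors, mappability
structure and FFPE artifacts none of which are simulated; and the observed
cross-platform TMB concordance of a real cohort depends on platform-private
calls the generator only models parametrically.

## Numerical choices and degenerate inputs

Alignment ties break to the leftmost target coordinate; assembly output is
sorted (length-descending, lexicographic); gap-fill base votes tie-break
lexicographically; empty sequences, malformed intervals, rank-deficient
catalogs, inconsistent clone trees (child VAF above parent) and infeasible
gene packings raise errors early. NNLS residuals are reported, not
thresholded. Display rounding is two decimals; raw values are kept
internally.

## Known limitations

Single best segment per alignment diagonal (sufficient for the near-exact
rules implemented, not a general aligner); no reverse-complement read
handling in assembly (generator reads are forward); the in-frame call treats
the gene body as CDS (no UTR model); the CLI exposes stage-level commands
only, with the finer-grained operations available as library functions and
analysis drivers.
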