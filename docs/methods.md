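# Methods

This note documents the models, rules, and numerical choices behind
`tnscreen`, and what the synthetic-data generator does and does not emulate.

## Coordinate and site conventions

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted once, at `load_annotation`.  A TA "site" is the
0-based position of the T on the forward strand.  TA is its own reverse
complement, so a single forward-strand position represents insertions
recovered from either transposon orientation; strand is a property of the
mapped read, never of the site.  These conventions remove any off-by-one
ambiguity from the first-95% rule below.

## Duplicated TA sites

Junction reads carry a 14 bp genomic tag, so two sites are indistinguishable
when their 14-mer contexts coincide.  Each site has two contexts — the
14-mer starting at the T (forward orientation) and the reverse complement of
the 14 bases ending at the A (reverse orientation) — because inserts are
recovered from either side of the transposon.  A site is *duplicated* when
either of its contexts occurs as either context of any other site, across
all replicons.  On circular replicons the contexts wrap across the origin;
on linear replicons a site within 12 bp of the relevant end has that context
undefined and is conservatively treated as duplicated.  Whether a
single-orientation definition would be more faithful to any particular
aligner's behavior is not decidable from the protocol alone; both-orientation
is the conservative choice and the k-mer length (14) is a module constant.

## Read processing

Processing follows the orientation dance of adapter/junction trimming tools:

1. truncate at the leftmost approximate adapter match (Hamming distance ≤ 2
   over the adapter length; no indels).  A read without an adapter match is
   kept whole — the junction match in step 2 is the mandatory anchor;
2. reverse complement, truncate at the leftmost approximate junction match
   (reject `no_junction` otherwise), reverse complement back;
3. drop the 4-base inverted-repeat remnant;
4. quality-truncate: with window 1, cut immediately before the first base
   below Q20 (general window sizes use the window mean);
5. keep TA-initial inserts of 14–18 bp; anything else is rejected with a
   specific reason (`quality_fail` when quality truncation shortened the
   insert below the minimum, then `non_ta_start`, then
   `length_out_of_range`).

Every input read ends in exactly one counter (accepted or one rejection
reason), so totals always reconcile.  Approximate matching is
Hamming/leftmost: an exact occurrence only wins if no earlier alignment is
within the mismatch budget.

The default adapter is the universal Illumina adapter prefix
(`AGATCGGAAGAGC`); the default junction is a 23 bp mariner-style
inverted-repeat segment containing the MmeI recognition site
(`CGGGGACTTATCATCCAACCTGT`).  Both are configuration — the exact construct
sequences belong to the experiment.  The junction anchor must be long
relative to the mismatch budget: a very short junction (e.g. the bare 6 bp
MmeI recognition sequence) with 2 allowed mismatches matches spuriously
inside genomic inserts at a rate of several percent per position and
corrupts extraction.

One consequence of honest adapter trimming: a genomic insert whose 3' end
resembles the adapter start can form an early within-budget adapter match
and be over-trimmed, losing that site's reads in one orientation.  This
affects of order 1 in 10³–10⁴ sites and is inherent to the protocol, not an
implementation artifact.

## Mapping

Inserts are 14–18 bp and must match with 100% identity at a unique genomic
location, so the engine is an exact-occurrence lookup, not a general
aligner.  Any genomic occurrence of a TA-initial insert necessarily starts
(forward strand) or ends (reverse strand) at a TA site, so the per-site
14-mer contexts double as a complete occurrence index for insert-shaped
queries; arbitrary queries fall back to a direct scan, and both paths agree
(property-tested).  More than one occurrence over both strands — including a
palindromic insert matching both strands of one locus — is `multi` and
discarded from counts but tallied; zero occurrences is `unmapped`.  Reverse
hits report the TA position at their right edge, so both orientations of one
insertion event collapse to a single site.  Occurrence lookup is linear in
the replicon sequence; inserts spanning a circular origin are not resolved
(the generator never samples sites that close to a sequence end).

## Per-gene counting and normalization

A site belongs to a gene when its T position lies in `[start, end)`; a site
inside overlapping genes credits each of them (the protocol provides no
disambiguation rule).  The *first 95%* of a gene is offset
< floor(0.95 × length), with offset `p − start` on the + strand and
`(end − 2) − p` on the − strand — floor plus strict comparison is the
conservative reading of "the last 5% is omitted".  Only non-duplicated sites
in the first 95% contribute to a gene's raw count.

Genes are excluded, with precedence, when they have no TA sites
(`no_ta`), none in the first 95% (`no_ta_first95`), or strictly fewer than
half their TA sites unique (`under_half_unique`; exactly half passes).

Raw counts become RpK = raw / (length/1000) — the denominator is the full
annotated length, not 95% of it — and are scaled to a common library size of
10⁷ uniquely mapped reads, counted jointly over all replicons:
normRpK = RpK × 10⁷ / N_unique.  normRpK is scale-invariant under uniform
rescaling of counts and strictly monotone in raw reads.

## Essentiality classification

Per replicate, the log₂(normRpK) values of countable genes (not excluded,
raw > 0) form an approximately normal distribution.  The fit is an
outlier-trimmed moment fit:

- **Trimming**: one pass of Tukey fences at Q1 − k·IQR and Q3 + k·IQR with
  k = 3 ("far outliers"), quartiles by linear interpolation.  With zero IQR
  (all values equal) nothing is removed; fewer than 4 finite values is an
  error.  The trimming rule is a free design choice (the statistical recipe
  only requires that outliers be removed before fitting); k is configurable
  and the choice is recorded in the run's provenance.
- **Fit**: sample mean and SD (n−1 denominator); zero variance is an error.

Categories by z = (value − μ)/σ: Essential below −3 (strictly — the region
below the interval covering 99.7% of a normal), GrowthDefect in [−3, −2),
NonEssential in [−2, 2], GrowthAdvantage above 2.  The intervals partition
the line and are monotone in the value.  Zero-read genes never enter the fit
(log₂ 0 is undefined) and are Essential categorically — a transposon hit in
a truly essential gene leaves no surviving reads.  No multiple-testing
correction is applied; the SD thresholds are the method.

Replicates combine by unanimity: any disagreement yields Uncertain.  For all
cross-condition set algebra, "essential" means consensus Essential only —
not GrowthDefect, not Uncertain.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

- **Genome**: i.i.d. bases at 64% GC (the screened organism's composition;
  TA density ≈ 0.032/bp), a ~4.27 Mb chromosome plus a 128 kb plasmid, both
  circular; 4,000 non-overlapping genes with uniform lengths 200–1,600 bp on
  random strands, each guaranteed ≥ 5 TA sites (deficient segments are
  redrawn).
- **Library**: each TA site is mutagenized with probability 0.5 (echoing
  observed per-library coverages around half of all sites); each mutant's
  pre-selection abundance is Exponential(1), the simplest heavy-ish-tailed
  model of clone-size spread after pooling.  Selection acts multiplicatively
  on abundance *before* reads are drawn: first-95% sites of essential genes
  → 0, growth-defect genes × 0.05, growth-advantage genes × 4; intergenic
  and trailing-5% sites are untouched.  Class fractions default to
  13/3/82/2% (essential/defect/neutral/advantage), approximating a dense
  bacterial screen without copying any one dataset.
- **Replicates**: independent multinomial draws of 2×10⁶ reads over the
  post-selection abundances — replicate noise is purely counting noise,
  consistent with replicates being outgrowths of a single selected pool.
- **Reads**: per sampled insertion, a forward read
  `[revcomp(junction)][IR remnant][insert][adapter][random filler]` at
  uniform Q30, strand by fair coin; reads from one site are identical
  templates (as PCR amplicons are).  Options plant a fraction of low-quality
  tails (exercising the quality gate) and substitution errors.  Sites too
  close to a replicon end for a full-length insert are excluded from
  mutagenesis up front — distributionally equivalent to resampling such
  reads, and it keeps the truth ledger exact.

Everything is a pure function of (config, seed); outputs are byte-identical
across runs.  The truth ledger records gene classes, per-site abundances,
and the exact per-replicate draws, so tests compare every stage against
planted truth rather than against the implementation itself.

What the generator does **not** emulate: realistic base-error profiles, PCR
duplicates and chimeras, positional insertion bias, bottleneck genealogies
across outgrowths, rRNA/tRNA features, or overlapping genes.  Passing
recovery tests therefore demonstrate correctness of the pipeline's logic
under the stated statistical model, not robustness to every artifact of real
libraries.

### Recovery behavior at the default scale

At the defaults above (measured by the test suite's full-scale run), the
pipeline recovers essentially all truth-essential genes (≥ 99.8%) and keeps
the Uncertain rate near 2%.  Truth-neutral recovery sits just below 95%
(≈ 93–95% across seeds): a ~1% sliver of short genes has all of its ~5
unique first-95% sites miss mutagenesis at density 0.5 and is called
Essential by the zero-read rule; a ~1–2% sliver sits at the ±2 SD
boundaries and flips between replicates (Uncertain) or lands in the
GrowthDefect band because a handful of Exponential(1) clone sizes summed
badly.  These are properties of the stringent SD-threshold method itself
under the stated library density and depth — the same conservatism the
method exhibits on real data — not of the implementation.

## Problem sizes used by the test suite

Unit and property tests run on ≤ 50 kb genomes where brute-force oracles
(quadratic all-pairs duplicate detection, exhaustive occurrence scans,
per-position interval scans) are exact and fast.  The end-to-end recovery
test runs the generator's full default conditions — 4.4 Mb genome, 4,000
genes, 3 replicates × 2×10⁶ reads — which completes in about a minute on a
single CPU thanks to memoized read extraction and placement (extraction and
mapping are pure functions of read content, and deep libraries repeat the
same junction fragment many times).

## Known limitations

- The multi-hit rule (">1 combined occurrence across strands") is one
  defensible choice; short-read aligners differ in how they treat
  equal-score opposite-strand hits, so absolute duplicated-site and
  multi-mapping counts can differ slightly from any particular aligner.
- The outlier rule before the normal fit is unconstrained by the statistical
  recipe; essential-gene sets on real data can be mildly sensitive to it.
  The rule and its k are therefore explicit configuration recorded in
  provenance.
- Reads spanning a circular origin are not mapped.
- rRNA/tRNA exclusion is an annotation-level concern left to the caller
  (filter the gene list before tabulation).
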