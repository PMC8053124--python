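# Methods

`rearescan` asks one question of a genome: do binding sites for two
transcription factors — the p63 response element (RE) and the NRF2
antioxidant response element (ARE) — co-occur closer together than uniform
chance would put them, and where do the resulting composite "RE-ARE"
elements sit relative to active chromatin and genes?  This note describes
the model behind each stage, the parameters that matter, the synthetic
data the package validates itself on, and the numerical choices made where
the design was genuinely open.

## Motif model

Binding sequences are degenerate IUPAC consensus strings matched *exactly*:
a window is a hit iff every base belongs to the character class of the
code at its position.  There is no position-weight-matrix scoring and no
score threshold; the consensus itself is the model.  Consequences:

- Both strands are scanned by default.  A reverse-strand hit is reported
  at its forward-strand coordinates with strand `-`.  p53-family REs and
  AREs are functional in either orientation, so neither strand is
  privileged.
- `N` in the genome matches nothing, not even pattern `N`.  Assembly gaps
  must not generate hits.
- A window matching the pattern on both strands (a pattern palindrome)
  yields two hits.  This is deliberate — the double hit is real
  information about orientation ambiguity — but it changes totals, so a
  `collapse_palindromes` flag collapses same-interval hits when a
  one-per-locus count is wanted.  Note that the shipped default RE
  placeholder (`RRRCWWGYYYRRRCWWGYYY`, the canonical p53-family element of
  two RRRCWWGYYY decamers) is *its own reverse complement as a pattern*,
  so every RE instance double-counts unless collapsed.
- Overlapping hits of the same motif are all kept; downstream
  nearest-neighbor pairing needs the complete hit set.

The shipped RE/ARE strings are documented placeholders
(`RRRCWWGYYYRRRCWWGYYY` and the classical ARE core `TGACNNNGC`).  Any
consensus can be supplied through the motif configuration file
(`name<TAB>pattern`); reproducing published genome-wide totals requires
the originally used consensus strings and genome assembly as inputs.

## Spacer definition and pairing

The distance between an RE and an ARE is the **inner gap** between the two
motif intervals — the number of bases separating the core sequences — not
a center-to-center distance.  For intervals `[s1, e1)` and `[s2, e2)` the
gap is `max(s2 - e1, s1 - e2)`; it is negative when the motifs overlap.
The inner gap is the quantity the steric rule applies to (see below), which
is why it was chosen over the center distance.

Pairing is RE-driven and many-to-one: each RE is joined to the ARE on its
chromosome minimizing `|gap|`; AREs (which outnumber REs roughly 8:1
genome-wide) may serve several REs.  Ties go to the lower-coordinate ARE.
A greedy one-to-one mode (assignments fixed in order of increasing
`|gap|`, each ARE used once) is available for sensitivity analysis.
Strand is ignored for pairing.  The gap is measured between the *full*
IUPAC matches; if a user's consensus includes flanking degenerate
positions beyond the core, spacers shift accordingly.

**Steric feasibility.**  Structural modeling of the p63 tetramer and the
NRF2–small-MAF dimer on nucleosomal DNA implies both factors can bind the
same composite element only when the spacer exceeds 7 bp.  The filter is
strict: spacer 8 is feasible, 7 is not, and overlapping pairs (negative
spacer) never are.  The threshold is a config field, default 7.

## Randomized-genome null

The control distribution is a hypothetical genome with the *same number*
of RE and ARE motifs placed uniformly at random, allocated to chromosomes
in proportion to length.  Design choices:

- **Largest-remainder allocation** rounds proportional quotas to integers
  that sum exactly to the requested total (ties broken by input order).
  Exact conservation is the point of the null.
- The null is **positional only**: no nucleotide sequence is realized,
  because only inter-motif distances are consumed.
- Overlaps among random motifs are permitted (a pure uniform process).  An
  optional non-overlap mode draws disjoint placements directly by gap
  insertion — sorted uniform draws over the free space, each start shifted
  by the room its predecessors occupy — which samples uniformly from the
  non-overlapping configurations without rejection and detects infeasible
  requests deterministically.
- One global seed feeds per-chromosome, per-motif-role substreams
  (`SeedSequence(entropy=seed, spawn_key=(role, chrom_index))`), so
  placements are reproducible and independent of iteration order.

Under this null, the nearest-neighbor distance from a point to `n`
uniform points on a chromosome of length `L` has
`P(d <= x) = 1 - (1 - 2x/L)^n`, approximately exponential with mean
`L/(2n)`.  The test suite checks the simulator against this closed form
with a KS test on an n = 10,000 sample *pooled from 50 independent
placements*: distances sampled within a single placement are not iid
(two queries falling in the same inter-ARE gap are correlated), and the
measured effect of that dependence is a fattened lower tail of the KS
p-value distribution, so pooling across placements is required for a
calibrated test.

## Distance statistics

Two summaries compare experimental against null distances (the same
routines serve motif spacers and pair-to-TSS distances):

- **Window enrichment**: the fraction of distances `<= w` (inclusive),
  default window 2000 bp, reported for both samples with their difference.
- **Two-sample Kolmogorov–Smirnov test**: D is the exact supremum of the
  ECDF difference over the merged sample support (ties handled by exact
  ECDF evaluation — distances are integers and heavily tied).  The
  p-value uses the asymptotic Kolmogorov distribution
  `Q(lambda) = 2 * sum_k (-1)^(k-1) exp(-2 k^2 lambda^2)` evaluated by the
  alternating series for `lambda >= 1.18` and the Jacobi-theta dual form
  below it, with the Stephens finite-sample correction
  `lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D`, `ne = n1 n2/(n1+n2)`.
  `lambda_correction=False` gives the uncorrected `sqrt(ne) * D`
  convention of R's `ks.test`.  The asymptotic form is appropriate here
  because genome-scale samples run to the thousands; a permutation option
  exists for samples under ~50.  By default the KS test compares the full
  distance distributions; a mode restricting both samples to the
  enrichment window first is provided.

Reported p-values are displayed with a floor of 2.2e-16 (the conventional
smallest value R prints) but stored at full precision.  Type-I error of
the default test, measured by the suite on 200 same-distribution replicate
pairs of n = 500 null spacer samples, is 5-6%.

## Peak annotation and gene association

A pair is "below" a ChIP-seq peak iff **both motif intervals are fully
inside** the peak's containment interval; since the pair span is the hull
of the two motifs, span containment is equivalent and is what is computed.
The containment interval defaults to the reported BED range; a
`center_window` mode uses peak center ± 300 bp instead, reflecting how
H3K27ac peaks are defined by read enrichment within 300 bp of the peak
center.  Both are implemented because peak files in the wild carry ranges
produced under either convention; the choice is a config field and is
logged.

A pair under several overlapping peaks counts once per peak in peak-level
statistics but once in pair-level statistics, keeping "percentage of
peaks with a pair" well-defined.  Peaks containing a lone RE or ARE (no
complete pair) are tracked separately.

Cross-state comparison (e.g. proliferation-competent vs differentiated
keratinocytes) partitions each state's RE-ARE-containing peaks into
*unique* and *common*: common iff the peak shares at least one base with
any RE-ARE-containing peak of the other state (half-open intervals, so
bookended peaks do not overlap).  A reciprocal-overlap criterion was
considered and rejected as under-specified; any-overlap is the documented
rule.

Gene association is GREAT-style closest-gene: each RE-ARE-containing peak
takes the TSS nearest its *center*, if within 100 kb (boundary inclusive:
99,999 bp qualifies, 100,001 does not).  The center anchor matches
GREAT's single-point convention; the paper trail for edge-anchored
alternatives was judged weaker.  When a peak contains k pairs its gene is
listed k times ("assigned in duplicate"), so ontology input downstream
weights genes by the number of composite elements driving them.  TSS
tables are 0-based by default with a 1-based dialect flag, since public
TSS lists come in both conventions.

## Synthetic worlds

The generator emulates the three inputs of the real analysis — genome
FASTA, peak BED, TSS table — with machine-readable ground truth, so every
stage is testable without downloads.  Defaults are the package's
validation conditions: one 5-Mb chromosome at GC 0.41 (human-like), 500
planted composite elements with spacers ~ Normal(100, 10) truncated at 0,
RE/ARE order randomized 50/50 per locus, peaks covering half the planted
pairs padded 100 bp beyond the span, and 50 TSS at uniform 1–50 kb
distances from pairs.  Planted loci are packed by gap insertion with a
minimum inter-locus gap (default 2 kb) so nearest-neighbor pairing
recovers each planted partner rather than a neighbor's motif.

Truth exactness is enforced in two passes: the background is generated
with all windows matching either motif (both strands) redrawn until clean,
and after planting, any incidental match straddling a planted-motif
boundary has its background bases redrawn ("junction scrub").  Residual
matches after the retry caps are warned about and counted.  A dirty-
background mode skips the scrubbing for realism.

What the synthetic world does *not* emulate: real base composition
structure (isochores, repeats, CpG islands), clustered or
chromatin-correlated motif placement, peak-width and peak-shape
distributions of real ChIP-seq, and gene density gradients.  Passing
tests therefore demonstrate the *correctness of the measurement
machinery* (scanning, pairing, statistics, containment, association) and
its calibration under the stated null — not that any particular real
genome shows the effect.

## Problem sizes and determinism

The validation suite runs at desk scale: 10-kb sequences for scanner
oracle equivalence (50 x 5 motifs), <=200-hit instances for pairing brute
force, a 100-Mb single-chromosome null for spacing calibration
(n = 10,000 pooled), 200 replicate pairs of n = 500 for KS type-I error,
and twenty 5-Mb planted worlds for signal recovery.  These sizes were
chosen so the full suite completes in a few minutes while keeping every
statistical check at meaningful power.

All randomness in the package flows from integer seeds through numpy
`SeedSequence` substreams.  Identical config (including seed) produces
byte-identical output files, which the suite asserts at the file level.

## Known limitations

- Exact consensus matching cannot express graded affinity; a weak site
  one mismatch away from consensus is invisible.
- The uniform null ignores sequence composition: AT-rich consensus
  strings are over-matched in AT-rich genomic regions relative to the
  null, which has no notion of local GC.  A GC- or chromatin-matched null
  is out of scope.
- The one-to-one pairing mode is greedy, not an optimal bipartite
  matching; with heavily shared AREs the greedy solution can differ from
  the global-minimum-cost matching.
- Gene association uses straight-line distance to the closest TSS;
  enhancer-promoter contact maps would reassign a fraction of peaks.
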