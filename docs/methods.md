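# Methods

## The bias being quantified

SMART (template-switching) DNA library preparation replaces adapter ligation
with two enzymatic additions: terminal deoxytransferase (TdT) appends a poly
dT tail to each fragment's 3' end, and a poly dA primer anneals to that tail
to start second-strand synthesis. When tailing is incomplete, fragments that
already contain a genomic poly dT run are captured preferentially, and the
primer may anneal to a run *inside* the fragment rather than to the appended
tail. The observable consequences in aligned paired-end data are:

1. second-read 3' ends ("tail ends") piling up immediately 5' of genomic
   poly dT runs on the forward strand and poly dA runs on the reverse strand
   (the reported sequence is always the forward strand, so a reverse-strand
   poly dT maps to poly dA);
2. fragments whose tail ends abut such runs being shorter than the rest,
   because internal annealing truncates the insert;
3. many fragments sharing *exactly* the same tail-end coordinate (clusters),
   since a given run pins every internally primed fragment to one base.

`smartbias` measures all three signatures, provides nulls to calibrate them,
and implements the mitigation: removing reads adjacent to mismatch-tolerant
poly dA/dT tracts.

## Coordinate and adjacency conventions

All coordinates are 0-based half-open (BED). The *tail end* of a `+`
fragment is its `end` coordinate; of a `-` fragment its `start`. A fragment
is *adjacent* to a tract at distance d when the tract interval overlaps the
fragment span extended by d bases on the tail side — for `+` fragments
`[start, end + d)`, for `-` fragments `[start - d, end)`. At the default
d = 1 this reproduces `bedtools window -r 1 -l 0 -u` (forward) and
`-r 0 -l 1 -u` (reverse) exactly, including the boundary case of a tract
beginning at the base immediately after the tail end; the test suite asserts
equality against `bedtools` on a boundary fixture. The vicinity mode
(`end="first"`, d typically 250) anchors the window at the first-read end
and reaches d bases toward the tail side, which is how the bias is detected
when only single-end (read 1) data exist: the priming site lies up to one
insert length downstream of read 1.

Adjacency counting is by sorted-interval bisection per (chromosome, base);
tracts of one base are disjoint, so both endpoints arrays are sorted and
each query is two binary searches. A fragment counts at most once per
(base, exact tract length) and once per base in cumulative (>= L) counts,
bucketed by the longest tract it touches so cumulative counts never double
count.

## Tract detection

*Exact* tracts are maximal single-base runs of length >= `min_len`; `N`
never matches. *Tolerant* tracts generalize this for the filter: a window
qualifies when it is >= `min_len` long, starts and ends with the tract base
(mismatches cannot pad edges), contains at most `max_mm` other bases and no
`N` (an unknown base is not evidence of a tract). The reported intervals are
the union of all qualifying windows, merged when overlapping or touching;
positions covered by the output are exactly those covered by some
qualifying window, which is the predicate the downstream filter needs. With
`max_mm = 0` the tolerant scanner reduces to the exact one. The
implementation finds, per qualifying start, the furthest end satisfying the
mismatch and N budgets via prefix sums and binary search (O(n log n)
overall); a brute-force window-enumeration oracle validates it on random
sequences.

The census tallies exact maximal tracts by base and exact length, exposing
both exact-length and cumulative counts (and base-pair coverage) so either
reading of a length threshold is available. Census counts are the expected
weights of the goodness-of-fit test below.

## Statistics

**Enrichment and effect size.** Per (base, strand): the count of fragments
adjacent to tracts >= 12 bp, scaled to per-million-fragments, divided by the
genomic number of such tracts. The canonical unit is therefore "fragments
per million per genomic tract". Deviation of the observed 4-base count
vector from census-expected proportions is summarized per strand by a
chi-squared goodness of fit; because p-values saturate at sequencing depth,
the headline number is Cramér's phi, `phi_c = sqrt(chi2 / (N (k-1)))`, with
N the total adjacent count and k the number of categories. Categories with
zero census weight and zero observations are dropped (k reduced and
recorded); a zero-weight category with observations is an error. The joint
8-category (base x strand) variant sits behind a flag.

**Fold-ratio-by-length curve.** The forward/reverse count ratio per base and
tract length (reverse/forward for A, mirroring the strand asymmetry of the
mechanism). Zero denominators get a +1/+1 pseudocount and a flag; points
whose paired counts sum below a configurable threshold are flagged `sparse`,
since a ratio of two small Poisson counts is noise. In an unbiased library
all reliable ratios sit at 1; under internal priming the T (and mirrored A)
ratios jump at the priming length threshold.

**Information content.** Base frequencies of the forward-genome sequence in
a 2w-bp window (default w = 10) centered on sampled end coordinates, per
strand, with `bits = 2 - H` (Shannon entropy, base 2) per column. Sampling
is 1,000 ends by default, seeded. No small-sample correction is applied; at
n = 1,000 it would be < 0.01 bit.

**Fragment lengths.** Welch's unequal-variance t-test comparing fragment
lengths split by tail-end adjacency to poly dA/dT tracts >= 12. Two
constant, equal groups return t = 0, p = 1 rather than a 0/0.

## Null models

**Shift randomization** translates every fragment by a fixed offset
(defaults 500, 1,000, 10,000), wrapping circularly within its chromosome;
fragments that would straddle the origin after wrapping are dropped and
counted (wrapping preserves library size and per-chromosome counts; the
retained set is >= 99% for offsets far below the chromosome length).
Shifting destroys sequence-specific positioning while preserving lengths,
strands and inter-read structure, so tract adjacency measured on shifted
data estimates the unbiased background. Note a structural property:
because the offset is constant, *exact-coincidence cluster fractions are
invariant under shifting* — every tail end moves by the same amount, so
ends that coincided still coincide. The shift null therefore calibrates
adjacency, not the cluster diagnostic; breaking clusters would require
per-read randomization, which this package deliberately does not conflate
with the structure-preserving shift.

**Random fragments** draws n fragments with starts uniform over the genome
and lengths resampled from an observed length list (no parametric fit), and
reports the fraction overlapping any poly dA/dT tract >= 12 — the chance
rate against which the observed adjacent fraction is compared.

## The filter

`filter_reads` removes every fragment whose tail-side window (same
adjacency arithmetic, distance 1) touches a tolerant poly dT tract for `+`
fragments or poly dA for `-` (length >= 12, up to 2 mismatches by default).
Strand-specific removal matches the mechanism; a `both_strands` flag gives
the conservative variant. The removed set is returned for auditing, and the
report carries the removed fraction plus coincident-end cluster fractions
before and after. Filtering is idempotent, monotone in its parameters
(looser length / more mismatches / larger distance remove more), and on
simulated libraries removes a superset of the truth-labeled internally
primed fragments, since every simulated priming site is an exact run >= 12
and the tolerant tract set contains every exact tract.

Hygiene filters applied before any statistic: exact-coordinate duplicate
removal, then removal of all fragments at tail-end positions hosting more
than 100 ends (repetitive-sequence proxy; exactly 100 at a position are
kept). The cap is per exact position by default — the strictest reading —
with a per-strand variant. Multi-mapping exclusion for BAM input uses a
mapping-quality threshold (default MAPQ >= 10), since "uniquely mapped" is
aligner-specific.

## The simulator and what it does (not) emulate

`make_genome` produces an i.i.d.-background genome in which every accidental
homopolymer run of >= 8 bp is broken by resampling (replacement bases always
differ from both neighbors, so fixes cannot seed new runs), then plants
tracts at known, non-overlapping, flank-separated positions. All long runs
are therefore planted and the truth list is exact: scanning the FASTA
recovers it bit-for-bit, which the tests assert. Default planting rates per
Mb are A: 330, T: 330, C: 3.3, G: 3.3 — the ~100:1 A/T vs C/G skew of
mammalian genomes (a consequence of retrotransposon poly-A integration) at
a density of roughly one A or T tract per 3 kb; planted lengths are
8 + Geometric(p = 0.35), capped at 30, so tracts >= 12 are well represented.
Tracts stay 2 kb from contig ends so anchored fragments never fall off.

`simulate_smart_library` draws fragments uniformly on both strands with
lengths ~ Normal(220, 60) truncated to [read length, mean + 5 sd] — a
sonication-like distribution bracketed by the adjacent/non-adjacent group
means observed in real libraries — and 2 x 50 bp reads. With probability
`p_internal` a fragment is captured at a qualifying genomic run (poly dT
>= 12 in tail orientation: T tracts for `+` fragments, A tracts for `-`),
chosen uniformly; its tail end is placed against the run's 5' edge and its
length reduced by 40 bp (never below the read length), modeling the
truncation internal annealing imposes. Drawing the internally primed
fragment conditional on containing a run reflects the mechanism —
fragments already carrying poly dT are the ones captured without tailing —
and makes the truth-label internal fraction equal `p_internal` in
expectation, which is what parameter-recovery tests measure against.
`simulate_ligation_library` is the identical process with the mechanism off:
the unbiased negative control. Reads are emitted error-free; a configurable
`p_gap` plants a 1-bp deletion in one read per flagged fragment for the
gapped-alignment diagnostic. `p_internal` is a free parameter swept in
tests, not an estimate of any kit's true tailing-failure rate.

What the simulator does *not* emulate: PCR duplication and GC amplification
bias, sequencing error, mappability structure, repetitive elements, real
tract length distributions, or the RNA-seq variant of internal priming.
Passing tests on this generator demonstrate that the measurement machinery
is correct and calibrated under a controlled version of the mechanism —
not that any particular real library carries a bias of a given size.

## Problem sizes and numerical choices

Validation runs use a 1 Mb genome, a 1 M-fragment unbiased library for null
behavior (per-strand phi < 0.05; reliable fold ratios within 10% of 1), and
200 k-fragment SMART libraries across `p_internal` in {0, 0.05, 0.15, 0.30}
for parameter recovery — sizes at which the binomial noise on an adjacent
fraction is ~10^-3, an order below the smallest planted effect. Two
statistical subtleties are handled explicitly. First, ratio points backed
by few tracts (C/G runs >= 8 are ~1 per Mb by construction of the skew) are
flagged sparse rather than asserted against a band their sampling noise
cannot meet. Second, after a constant shift, all internally primed
fragments anchored at one tract move in lockstep, so whether their windows
hit a tract is one Bernoulli draw per *anchor*; the shift-null comparison
therefore uses the anchor-level variance
`Var(m) = bg(1-bg) * sum_a w_a^2` (w_a = anchor weight) plus the ordinary
binomial term for independent fragments, rather than a per-fragment
binomial SE that would understate the variance ~15-fold.

Degenerate inputs: empty fragment sets are errors for fractions
(cluster/enrichment) rather than silent zeros; zero-census bases yield
flagged-NaN normalized values, never 0; `N`-containing windows are
disqualified in tolerant scanning; all generators and samplers are
deterministic given a seed.

## Known limitations

- The tolerant-tract dialect (merged qualifying windows, edges forced to the
  tract base) is one defensible reading of mismatch-tolerant runs; other
  tools' degenerate-pattern scanners may report different interval sets with
  the same coverage semantics.
- The shift null cannot calibrate the coincident-end cluster diagnostic (see
  above); cluster fractions should be compared against an unbiased library
  or a per-read randomization performed outside this package.
- Single-end mode reduces a read to its own span; insert-size information is
  unavailable, so the 250-bp vicinity window trades specificity for recall
  exactly as in real single-end QC.
- The package quantifies and filters the bias; it does not correct counts in
  regions adjacent to poly dA/dT tracts, and the filter itself introduces a
  complementary bias against those regions, which the report quantifies but
  cannot remove.
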