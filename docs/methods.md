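# Methods

## Coordinate model

All internal coordinates are 0-based half-open (`[start, end)`), the BED
convention. FIMO TSV rows and any 1-based inclusive printed coordinates are
converted at the I/O boundary. All chromosome names are normalized into the
UCSC `chr` namespace on input so ENCODE/GEO/UCSC-style tracks can be mixed.
Readers reject structural errors (too few columns, start ≥ end, missing
FIMO strand column) with the offending line number rather than repairing
them silently.

## The loop caller

**Anchors.** An anchor is a cohesin peak that overlaps (≥ 1 bp) a CTCF peak
containing at least one CTCF motif hit with p ≤ `motif_pvalue_max`
(default 1e-4). The anchor inherits the cohesin peak's interval;
orientation and motif score come from the best-scoring motif among the
overlapping CTCF peaks. When several cohesin peaks overlap one CTCF peak,
each yields its own anchor — deduplication is deferred to the loop
redundancy stage. FIMO log-odds scores can be ≤ 0; when any usable score
is, all motif scores are shifted by `1 − min(score)` so geometric means are
defined. The anchor score is √(cohesin score × motif score).

**Pairing.** Within each chromosome, every (forward-motif, reverse-motif)
anchor pair with the forward anchor upstream and span ≤ `max_span` is a
candidate. The *minimum proportion* rule (default 0.40) is applied as
anchor balance within the pair: min(score_f, score_r) ≥ 0.40 × max(...).
This reading prevents pairings between a strong anchor and a much weaker
distal one, and is invariant to globally rescaling all scores — doubling
every peak and motif score leaves the accepted loop set unchanged and
doubles the combined scores. An alternative reading (each anchor must reach
40% of the chromosome-wide maximum before pairing) is selectable via
`CallerParams(pairing_rule="global_fraction")`. `max_span` defaults to
3 Mb, the upper end of typical TAD scale; it is a configuration value, not
a biological claim.

**Redundancy.** Two loops are redundant when they share the identical
upstream anchor interval and reciprocally overlap ≥ 0.98 in both
directions; the wider loop is kept. Collapse proceeds widest-first within
each upstream-anchor group to a fixed point; the operation is idempotent.
"Same upstream anchor" means the identical interval, not merely an
overlapping one.

**Scores.** A loop's combined score is the geometric mean of its two anchor
scores, which lies between them; summaries (count, median span, IQR) use
linear-interpolation (type-7) quartiles.

## Matching and condition comparison

The scalar `overlap_fraction` used for ranking candidates, and for the 75%
unchanged criterion, is the **minimum** of the two reciprocal overlap
fractions. It is symmetric, conservative (never larger than either
directional fraction), and makes the 95% complete-match rule a threshold on
the same statistic. Mean and query-directional variants are available via
`MatchParams(fraction_statistic=...)`.

For each query, all same-chromosome references overlapping ≥ 1 bp are
candidates; the best is the highest `overlap_fraction`, with ties broken by
larger raw overlap, then leftmost reference start — deterministic by
construction. Complete (both reciprocal fractions ≥ 0.95) is tested before
the partial subtypes, so two identical spans are complete, not
include/inside. Containment is non-strict; displacement direction is the
sign of (query midpoint − reference midpoint). Equal midpoints without
containment cannot occur for intervals of different lengths, so the
midpoint rule is total.

A condition comparison queries one loop set against the other and labels a
loop *unchanged* iff its best match's `overlap_fraction` is strictly
greater than 0.75; *different* loops split into unmatched versus
matched-below-threshold. Which set is the query is the caller's choice: the
pipeline's report queries control loops against the patient set, i.e. it
measures which control loops are no longer supported in the patient.
Integration of several samples' loop lists is the union with cross-set
redundancy collapsed by the caller's rule (intersection mode available).

Score distributions are compared with a two-sided rank-sum test. For pooled
n ≤ 20 the permutation distribution is computed exactly by a subset-sum
dynamic program over doubled midranks — equivalent to enumerating all
C(n, n₁) group assignments and tie-safe — and the smaller tail is doubled
(capped at 1). Larger samples use the normal approximation with tie
correction. Two samples with all values identical give p = 1 by definition.

## Spike-in calibration

Downsampling factors are `min(spike counts) / spike countᵢ`, so the
shallowest-spike sample has factor exactly 1. Thinning is per-read
independent Bernoulli (binomial thinning for count vectors), seeded and
reproducible; an exact mode keeps exactly `round(factor × n)` reads for
small deterministic tests. Bernoulli thinning differs from exact
hypergeometric subsampling only by O(√n) fluctuations, negligible at
sequencing depths. IP and input files are thinned independently with
recorded seeds. The IP/input scaling factor used by peak callers is
consumed as a user-supplied scalar, not estimated here. The peak filters
are strict: LFC > 5 (a fold change of exactly 5 is dropped) and
−log10(adjusted p) > 2 (adjusted p = 0.01 is dropped).

## Annotation statistics

Feature flags use the standard ≥ 1 bp overlap rule (a midpoint-in-feature
rule is a config switch). Promoters are TSS −1000/+100 bp strand-aware.
GC > 60% is computed from genome sequence under each peak, N bases excluded
from the denominator; an all-N interval has undefined GC. The TSS distance
is signed in gene orientation (negative upstream). The spacing null
re-places the same number of peaks per chromosome with preserved lengths
uniformly at random (no overlap constraint) and reports the add-one
empirical upper-tail p-value `(1 + #{null ≥ observed}) / (shuffles + 1)`.
Peak-to-peak distance defaults to midpoint-to-midpoint; an edge-gap
convention is available (the two agree for point-like peaks). Window
signals count read midpoints per position in ±500 bp around peak midpoints;
positions off the chromosome are NaN and excluded from the mean profile.

## What the synthetic data emulates — and what it does not

`plant_loops` writes, for each planted loop, a forward-motif anchor at the
span start and a reverse-motif anchor at the end: a 400 bp cohesin peak, a
500 bp CTCF peak, and a 19 bp centered motif (the CTCF core motif width)
with the planted strand. Anchor scores are drawn from the configured range
with the weaker anchor of each pair at ≥ 0.7 of the stronger — comfortably
above the 0.40 pairing rule, so the default multiplicative score jitter
(log-normal, σ = 0.1) essentially never breaks callability of a planted
loop. Loops are packed left to right with inter-loop gaps exceeding
`max_span`, which excludes cross-loop convergent pairs by construction;
consequently a noise-free run must recover every planted loop exactly, and
a recovered/not-recovered decision is unambiguous. Configurations whose
balance floor is below the pairing threshold are rejected.

`add_noise` inserts cohesin-only and CTCF-only decoy peaks (which cannot
form anchors by themselves), applies log-normal score jitter, and flips the
strand of an exact fraction of motif rows (sampled without replacement — a
derandomized perturbation, so the realized flip fraction equals the stated
one). Every perturbation is recorded; loops whose anchors are no longer
convergent or balanced are listed as destroyed. Recovery metrics
(`score_recovery`) therefore report recall against the still-intact planted
loops by default — a loop whose input signature was destroyed carries no
callable signal, and counting it against the caller would measure the noise
process instead — alongside `recall_all_planted` over every planted loop.

`make_patient` emulates impaired cohesin loading: a fraction of NIPBL-like
peaks disappears and a fraction of anchors loses its cohesin peak, whose
score mass reappears at CpG-island-like (or random) positions as
cohesin-only peaks. The affected anchors are a prefix of a seed-derived
permutation, so at a fixed seed the affected sets for increasing
redistribution fractions are nested and the number of destroyed loops is
non-decreasing — the dose–response is monotone per seed, not only in
expectation.

The generated sequence is i.i.d. per base (GC 0.40 background, 0.75 inside
islands, ~10 islands/Mb, lengths 500–2000 bp): composition is right, but
there is no dinucleotide structure, no repeats, no mappability variation,
and peaks/motifs are planted noiselessly at known positions. Passing
recovery tests therefore demonstrates the correctness of the algorithms on
data satisfying their assumptions; they say nothing about peak-calling
quality, antibody efficiency, or motif-scan sensitivity on real genomes.
Hi-C-style references are span lists with Gaussian boundary jitter and
exact-fraction false positives/negatives, not contact matrices.

## Problem sizes and determinism

The default test and acceptance scenario uses 40 planted loops per
condition across two 150 Mb coordinate spaces (sequence is only
materialized for Mb-scale annotation tests), five noise replicates, ~10⁵
reads per calibration sample and ≤ 199 spacing shuffles; the whole suite
runs in well under a minute. Every stochastic step takes an explicit seed
and is reproducible bit-for-bit; the pipeline writes a manifest (config
snapshot, input checksums, seeds, version) per run directory and skips
completed stages whose recorded input checksums are unchanged.

## Known limitations

- The caller enumerates convergent pairs per chromosome in O(F·R) per
  chromosome; adequate for desk-scale peak sets (tens of thousands of
  anchors), not optimized for pathological inputs with millions.
- Nested planted loops are supported by the classifier but the default
  generator plants non-nested loops; a nested mode stresses include/inside
  classification only in tests.
- BAM files are not parsed; reads are consumed as positional BED-like
  records. Alignment, duplicate marking, peak calling and differential
  M-A normalization are upstream of this package and consumed as inputs.
- The rank-sum exact path is O(n₁ · n · Σranks) via the DP; fine for
  n ≤ 20, by design not used above.
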