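# Methods

## Data model and coordinate conventions

All features — aCGH probes and expression probes alike — are genomic
intervals `(chromosome, start, end)` in 1-based inclusive coordinates, the
convention of array annotation tables: length is `end − start + 1` and the
overlap of two closed intervals is `min(ends) − max(starts) + 1` basepairs.
BED input (0-based half-open) is converted at the I/O boundary. Chromosome
labels are normalized on construction (an optional `chr` prefix stripped;
`X`, `Y`, `MT` uppercased) and compared by string equality. Midpoints
`(start + end)/2` are kept as exact halves; rounding them would silently
change which probe wins a distance tie.

The copy number platform carries three aligned feature × sample matrices:
`normalized` (noisy log2 ratios), `segmented` (their piecewise-constant
segmentation along the genome), and `calls` (the discretization into
−2…2, double loss through amplification). The expression platform carries
one matrix. Matching operates on the annotation only, with one deliberate
exception: overlapPlus consults the segmented data, which makes its matching
dataset-dependent — two datasets from the same platform pair can match
differently.

## Matching semantics and tie-breaking

All procedures are order-independent: candidates are scanned in
`(start, end, id)` order regardless of input row order, so permuting either
platform's rows permutes only indices, never identities.

- **distance** imposes no maximum distance (a gene whose chromosome carries
  a single CN probe still matches it), because completeness of matching is
  the procedure's defining property; matches beyond a configurable warning
  distance (default 1 Mb) are flagged in the result's notes, since a
  cis-effect across such separations is not plausible.
- **distanceAny** uses a *strict* midpoint-distance cutoff (`d < window`)
  and raw weights `1/(d + offset)` with `offset = 1` bp by default — the
  offset exists solely to keep a probe with midpoint exactly at the gene's
  from receiving infinite weight. Weights are normalized to unit sum inside
  the matching step, so every summary downstream is a plain weighted mean.
- **overlap / overlapAny** divide the shared basepairs by the *copy number
  probe's* length, never the gene's: a 60 bp oligo fully inside a 70 kb gene
  scores 1. The overlapAny threshold is strict (`fraction > min_fraction`,
  default 0); consequently overlap and overlapAny(0) always match exactly
  the same gene set and differ only in weighting.
- **Ties** (several probes equally near, or several fully contained probes
  all at fraction 1) break toward the smallest start, then smallest end,
  then lexicographic id. The worked-example locus exercises this: ten probes
  tie at overlap fraction 1 and the leftmost is selected.
- **overlapPlus** interpolation: for an unmatched gene the nearest flanking
  probes by midpoint (strictly below / strictly above the gene midpoint) are
  compared sample-wise on their segmented rows with absolute tolerance 1e-8
  — segmented data are piecewise constant, so true equality is exact and the
  tolerance only absorbs text round-trips. Interpolation assigns the nearer
  flank (distance tie → downstream). A gene with only one flank (chromosome
  end) stays unmatched: with no second anchor the absence of a breakpoint
  cannot be certified.
- **label** matching enforces nothing positional by design — descriptor maps
  can legitimately link features across chromosomes — but a strict flag can
  discard cross-chromosome links when annotations are supplied.

## Summarization

The weighted summary averages normalized and segmented rows with the match
weights, per sample; missing values are excluded and the surviving weights
renormalized within the sample, and a sample where every matched value is
missing stays missing. Calls are categorical and are never averaged: the
dominant-weight feature's calls row is copied. When several features tie for
the largest weight, the tie is resolved per sample toward the call nearest 0
(the conservative choice), then the smaller start — per sample because the
tied features' calls differ between samples.

The most-aberrant summary selects, per sample, the segmented value of the
matched feature with the largest |segmented| (ties → smaller start) and
carries that same feature's normalized value and call alongside, so each
output column is internally consistent. Its magnitude therefore dominates
the weighted mean's in every sample.

Splitting at breakpoints partitions each matched set, in genomic order,
wherever two consecutive members' segmented rows differ in any sample (same
1e-8 tolerance); part weights are renormalized. Expansion to singletons
gives every matched feature its own weight-1 entry. Both leave the
feature-to-gene assignment untouched and only change the summary; both can
make a gene recur in the matched dataset, which the provenance table (gene
id, CN ids, weights per row) records so downstream multiple-testing
corrections can count the recurrences.

Summary rows inherit the gene's own annotation: the signature is the dosage
assigned *to the gene*, and recurring rows are distinguished by provenance,
not coordinates.

## Cis analysis

Per matched row, Spearman's rank correlation between the expression
signature and the segmented copy number signature across samples (≥ 3
required), with average ranks for ties and the two-sided t approximation
for p-values — computed vectorized over rows, with a pairwise-complete
fallback for rows containing missing values. A row with a constant vector
carries no rank information: its correlation and p-value are reported
missing and it is excluded from the Benjamini–Hochberg denominator.
Significance is declared at BH-adjusted p < 0.05 by default. The association
test is deliberately the same nonparametric statistic used to compare
procedures; no parametric dose-response shape is fitted.

Procedure comparison counts, over the genes matched by *every* procedure
under comparison, how often procedure A's rho strictly exceeds B's; rank
ties count for neither side, so the two counts for a pair need not sum to
the number of genes.

## The simulator

`SimConfig` describes a paired-platform study; all randomness flows from its
single seed through one `numpy.random.default_rng` stream, so identical
configurations are bit-reproducible.

Per chromosome, segment borders are drawn once and shared across samples;
each (segment, sample) receives an aberration state — loss, normal, gain,
amplification with probabilities (0.15, 0.60, 0.20, 0.05) and log2 levels
(−0.45, 0, 0.45, 0.9), typical calling-threshold magnitudes for tumor
aCGH — giving exactly piecewise-constant segmented profiles whose
breakpoints sit where adjacent states differ. Normalized ratios add Gaussian
noise (sd 0.15, a mid-range array noise level); calls threshold the
segmented values at (−0.225, 0.225, 0.675), halfway between levels (the
double-loss level −2 is reserved but not emitted). Probes are placed one per
equal slot along the chromosome, uniformly within the slot, which guarantees
sorted, non-overlapping layouts; a probe longer than its slot is rejected as
infeasible. Two layouts mirror the two array generations: `oligo` (60 bp
probes; by default 2000 probes over 4 × 10 Mb, i.e. ~20 kb spacing,
Agilent-244K-like density) and `bac` (~150 kb clones; `bac_like_config()`
spaces them ~1.5 Mb apart, so probe midpoints usually sit far from gene
midpoints and narrow-window distance matching fails for most genes — the
qualitative behaviour of early BAC datasets).

Genes (default 500, 30 samples) have lognormal lengths (median 20 kb, shape
0.8, plausible for mRNA loci) and uniform starts. A fraction (default 0.3)
of genes is cis-regulated: `expression = baseline + beta × segmented(own
locus) + noise` with baseline N(7, 1), slope beta = 0.8 and noise sd 0.3 —
an effect around twice the noise at a gain, detectable but not trivial at 30
samples. Ground truth records each gene's cis flag and the CN probes
genomically overlapping it.

What the simulator does *not* emulate: scanner-specific noise, wavy
artifacts, segmentation errors (segments are known exactly, not estimated),
probe-level annotation errors, and per-sample breakpoint positions
(borders are shared across samples; only states differ). Passing recovery
tests therefore validate the matching and summarization logic under clean
segmentation, not robustness to preprocessing noise in real data.

## Validation strategy and problem sizes

Every procedure is checked against a naive exhaustive O(n·m) oracle on
seeded random instances (up to 200 probes × 50 genes; 200 instances per
procedure in the end-to-end suite), alongside the packaged worked-example
locus where every procedure's answer is known. Monotonicity of matched-gene
counts in the distanceAny window and overlapAny threshold is checked over
100 seeded instances. Parameter recovery runs 100 replicates of the default
simulation (500 genes × 30 samples): in at least 95 the mean |rho| of cis
genes must exceed that of non-cis genes after overlapAny matching and
weighted summarization. These sizes keep the whole suite under a minute on
one core while the oracle comparisons remain exhaustive.

## Known limitations

- Strand is ignored throughout, as is standard for copy number matching.
- Label matching quality is entirely that of the supplied descriptor maps.
- overlapPlus interpolates only between two flanks; chromosome-end genes are
  never interpolated.
- The cis stage tests monotone association only; nonlinear dose-response
  shapes (e.g. expression responding to amplification but not loss) are
  detected only insofar as they are monotone.
- The simulator's shared segment borders make breakpoints coincide across
  samples more than in real tumors, which slightly favours the
  breakpoint-split extension's clean partitions.
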