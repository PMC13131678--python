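# Methods

This note documents the models, conventions and numerical choices behind
`epinorm`, and what the synthetic-data tests do and do not establish about
real data.

## Signal representation

All signal is carried as run-length-encoded per-base tracks: per
chromosome, sorted non-overlapping half-open `(start, end, value)` runs
with implicit 0 elsewhere. Canonical form stores no zero-valued runs and
merges book-ended equal-valued runs. Two consequences are load-bearing:

- every stored run is a *maximal constant-value plateau* within its
  contiguous stretch, which makes the local-maximum definition exact; and
- all arithmetic (subtraction, masking, pooling, medians, quantification)
  is a sweep over the union of run breakpoints — exact per-base results
  with no binning anywhere in the pipeline.

Coordinates are 0-based half-open (BED/bedGraph convention) throughout.
Chromosome output order follows the chrom.sizes file, never the locale.
bedGraph is the bit-exact reference format (values are written with
shortest-round-trip float formatting so read∘write is the identity);
bigWig support is an optional convenience via pyBigWig.

## Coverage

Single-end mode counts each primary, mapped, MAPQ-passing read's aligned
span, optionally extended to a fixed fragment length from its 5′ end
(strand-aware, clipped at chromosome bounds); reads are *not* extended by
default. Paired-end mode counts each properly paired fragment once, from
the leftmost mate, as `[start, start + |TLEN|)`; pairs with TLEN 0 or
improper flags are skipped. Input BAMs are expected to be pre-filtered to
high-quality unique alignments; `mapq_min` is a convenience only
(default 0).

Control subtraction scales the control to the IP's counted-unit total
(totals-ratio) before per-base subtraction and clamps negatives to 0 by
default — the downstream percentile machinery assumes non-negative
coverage. Subtraction operates on raw per-base counts, before any
normalization of the IP itself. Blacklist masking zeroes signal inside the
given regions and is idempotent.

## Percentile-of-local-maxima normalization

A local maximum is a plateau whose value strictly exceeds the adjacent
signal on both sides, with flanks beyond the track or across
zero-coverage gaps valued 0 (so isolated peaks qualify). Evaluating the
strictly-greater rule at plateau level rather than per-base is the only
reading under which flat-topped integer coverage has maxima at all; it
degenerates to the per-bin rule when all runs are 1 bp.

Each plateau contributes one value, unweighted by width. `P99_s` is the
99th percentile (linear interpolation between closest ranks — numpy's
default estimator, recorded in the report) of those values. The printed
scaling factor is `SF_s = P99_s / P99_ref` with the reference being the
first sheet record of the target group; the *applied* multiplier is its
reciprocal, so post-normalization P99s are equal across samples by
construction (the report carries both, and `literal_sf` applies the
printed factor instead for users who want the literal formula). P99 ≤ 0
or an empty maxima list is an error naming the sample: such a sample
cannot be normalized.

**Assumption worth knowing.** P99 summarizes the top 1% of local maxima.
If differential regions are both strong and numerous enough to populate
that top tail in one condition (in the bundled demo: 10% of peaks at
4-fold), that condition's P99 partially tracks the biology rather than
the technical scale, and cross-condition multipliers absorb some true
signal. Two mitigations are built in: within-condition comparisons are
unaffected, and the count-level composition factors of the differential
stage re-center residual scale differences. This is also why the
differential stage offers `none` scaling for truly global unidirectional
changes.

## Built-in consensus caller and the grid

External narrowPeak/broadPeak files are the faithful path for peaks
(column 9 is −log10 q; the caller convention of −1 for "q not computed"
maps to unknown, and unknown-q peaks are excluded from every q-filtered
set). The built-in caller exists so the pipeline runs without external
binaries: genome tiled into fixed windows (narrow: 200 bp, broad: 500 bp),
each window's rounded summed signal tested one-sided against a Poisson
background whose mean is the genome-wide mean window signal (raised to the
depth-scaled control window mean where a control is given), BH adjustment
across all windows, significant windows merged (book-ended for narrow,
within two windows for broad). It is a deliberately minimal screening
device, calibrated for per-base-Poisson-like backgrounds; real fragment
coverage is overdispersed at window scale, so its precision on real data
is secondary to its recall — the grid's q filter is the user-facing
stringency control.

Grid construction: for each (q, d), filter each condition's peaks at
q ≤ threshold, concatenate across conditions (no per-condition provenance
in the merged output), sort, and merge regions whose gap ≤ d
(bedtools `-d` semantics: gap exactly d merges; d = 0 merges overlapping
and book-ended). Defaults are q ∈ {0.1, 0.05, 0.01, 0.001, 0.0001} and
d ∈ {0, 50, 100, 250, 500} bp → 25 candidate sets, both lists fully
configurable.

## Differential binding model

Counts are rounded sums of per-base normalized signal per region (sums,
not means, preserve width information). Low-count filtering keeps regions
with row total ≥ `min_counts` across all samples. Library sizes are
post-filter column sums.

Composition factors follow the edgeR convention — corrections *on top of*
library size, computed on depth-normalized counts, rescaled to geometric
mean 1, entering the model as offsets `log(factor_s · L_s)`:

- `rle`: median of each sample's depth-normalized ratios to the
  per-region geometric mean, over regions positive in all samples
  (errors out if no such region exists);
- `upperquartile`: 75th percentile of the sample's nonzero counts over
  its library size;
- `tmm`: trimmed mean of M-values against the sample whose upper quartile
  is closest to the mean upper quartile, trimming 30% of M and 5% of A,
  with the conventional precision weights (`rle` and `upperquartile`
  reproduce edgeR's `calcNormFactors` to 4 decimals on test matrices; the
  TMM recipe is within ~1–2%, not a line-for-line port);
- `none`: all 1. Library-size offsets are still applied with `none`;
  `use_offsets=False` drops offsets entirely for the near-complete-loss
  scenario.

Per region the model is `y_s ~ NB(mu_s, alpha)` with
`log mu_s = beta_0 + beta_1·1[condition B] + o_s` and variance
`mu + alpha·mu²`. Group intercepts are fitted by Newton iteration on the
NB score (Poisson-start, step-clamped, tolerance 1e-10); `log2FC =
beta_1 / ln 2`. Dispersion is a per-region pooled-within-group
method-of-moments estimate shrunk 50/50 toward the common dispersion and
floored at 1e-6. The common dispersion is the pooled ratio-of-moments
(sum of moment numerators over sum of denominators) across regions — the
median of clipped per-region estimates is biased low at small replicate
numbers, which measurably inflates the test.

The Wald statistic `beta_1 / se` uses the Fisher information of the two
group fits. Its reference distribution is Student t with the Satterthwaite
effective degrees of freedom of the half-weighted dispersion estimate,
`df = residual_df / 0.5² = 4·(S − 2)` for S samples in the contrast. With
few replicates the normal reference is anti-conservative because noise in
the per-region dispersion leaks into the statistic (with the true
dispersion the normal reference is well calibrated); the t reference
restores nominal behaviour under the generator's default conditions
(null type-I ≈ 0.05 at p < 0.05; BH-level FDR ≤ 0.10 with sensitivity
≈ 1.0 for 4-fold effects at region mean 200, dispersion 0.05, 4 vs 4 —
both recomputed by `scripts/acceptance.py`) and converges to the normal
as replication grows. Multiple testing is Benjamini–Hochberg; the |log2FC|
threshold is applied post hoc to the point estimate (a cutoff, not a
composite null). Regions with zero counts in both groups get p = 1;
group intercepts are floored at log 1e-8.

Method labels are presentation only: `deseq2-like` defaults to `rle`
scaling, `edger-like` to `upperquartile`; the engine is the single NB
Wald procedure above in both cases.

## QC

Mean per-base signal in fixed-width genome tiles (default 10 kb; terminal
bins keep their true width), log2(x+1) transform before PCA by default.
PCA is centered over bins; component signs are fixed by forcing each
component's largest-magnitude loading positive, so output is
deterministic. Correlation is Pearson or Spearman over bins;
zero-variance samples yield NA off-diagonals.

## Synthetic cohorts and what the tests show

The generator emulates the structure the normalization model assumes: a
shared landscape of non-overlapping peaks (lognormal widths, median 1 kb,
sigma 0.4) over uniform background (0.02 expected fragments/bp ≈ 4×
coverage at 200 bp fragments), 10-fold peak enrichment, per-sample global
depth multipliers, NB over-dispersion (0.05) on per-region fragment
counts, and condition-B fold changes (default 4-fold, alternating
gain/loss) in a seeded subset of peaks (default 20%). Output is SAM text
(plus sorted/indexed BAM via pysam in the CLI), truth BED + fold table,
and the exact expected-coverage bedGraph of the emitted fragments.

Two cohort flavours serve different claims. `simulate_scaled_cohort`
draws the fragment landscape once and multiplies it by per-sample
factors — the exact "shared latent signal × global scale" structure the
normalization method is built to invert — and is used for the
equalization/recovery guarantees (P99 equal to 1e-9 relative tolerance;
multipliers within 5% of the reciprocal factors on the standard 1 Mb /
300-peak / {1.0, 2.0, 0.5, 1.5} cohort). `simulate_alignments` samples
every sample independently and is used for end-to-end runs, where only
direction/recall-level claims are made.

Not modelled, hence not demonstrated by passing tests: read-sequence
realism, mappability and GC structure, fragment-length variation,
antibody efficiency differences that change peak *shape* rather than
scale, and window-scale overdispersion of real background (see the
built-in caller caveat). Problem sizes in the test-suite (0.15–1 Mb
genomes, 40–300 peaks, 2000-region count simulations) were chosen as the
smallest at which the statistical claims are stable.

## Determinism

Every stage is deterministic given (inputs, seed): per-sample random
streams derive from `SeedSequence(seed, spawn_key=...)`, dict iteration is
insertion-ordered, and output headers carry the tool version and analysis
parameters but no file paths, so two identical seeded runs are
byte-identical wherever they are written.
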