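# Methods

## Problem setting

At ~0.1X coverage, copy-number alterations (CNAs) are detected from the
*density* of aligned reads: the genome is tiled with non-overlapping
1 Mb bins and the reads starting in each bin are counted (~4,000 reads
per bin at 0.1X).  For DNA amplified from 1–5 cells, whole-genome
amplification (WGA) adds strong locus-specific multiplicative bias on
top of Poisson counting noise, and that bias — not sequencing depth —
is what limits the size of detectable CNAs.  The package implements the
full detection chain plus a generator of WGA-biased counts so every
stage can be exercised and calibrated without sequencing data.

## Count model of the generator

Per-bin counts are drawn as

    count_i ~ Poisson( N · (cn_i / 2) · b_i · g_i )

* `N` — expected reads per diploid bin (default 4,000).
* `cn_i` — truth copy number of bin *i*; an aberration covering a
  fraction *f* of a bin contributes `2 + f·(cn − 2)` (area weighting),
  which is how a 2.5 Mb deletion straddling three bins produces the
  intermediate ratios 0.625 / 0.5 / 0.625.
* `b_i` — log-normal multiplicative amplification bias with location
  `−σ_log²/2` so `E[b] = 1`; optionally AR(1)-correlated along each
  chromosome with coefficient `rho` (marginal σ preserved).  Log-normal
  mean-one bias is the standard minimal model for WGA; the AR(1) knob
  creates the *segmental* artifacts that turn into false-positive calls.
* `g_i` — optional GC tilt `exp(gc_slope · (GC_i − mean GC))`
  renormalized to mean 1; the simplest form the additive GC-LOESS stage
  can provably remove.

All randomness flows from one integer seed; replicate *r* of a study
uses `seed + r`.

### Calibration of the noise presets

For iid mean-one log-normal bias the mean-scaled profile variance is
`exp(σ_log²) − 1 + 1/N`.  `sigma_for_target_variance` inverts this, so
each named preset stores a target variance and derives σ_log at run
time: e.g. a target of 0.077 at N = 4000 gives σ_log ≈ 0.272
(SurePlex-like, 3 cells) and 0.138 gives σ_log ≈ 0.359 (MALBAC-like,
3 cells).  MALBAC presets additionally set `rho = 0.3`; the spatial
correlation of real MALBAC bias is uncharacterized, so `rho` is an
exposed free parameter, chosen once as a moderate value that produces
multi-bin artifacts without washing out the marginal calibration.

### Truth fixture

The packaged seven-region truth profile mirrors a female T-ALL line:
X monosomy, distal deletions of 72 Mb (chr5) and 45 Mb (chr6), a 2.5 Mb
deletion (chr9, deliberately bin-straddling), 13 Mb and 3 Mb deletions
(chr16 p- and q-terminal) and a 3 Mb duplication (chr13).  Sizes are
exact; positions approximate the cytobands on hg19 and are overridable
via a truth BED.  The packaged chromosome table (22 autosomes + X)
yields 3,030 1 Mb bins; trailing sub-bin chromosome ends are dropped so
every bin has equal width (a requirement of the equal-variance
statistics downstream).

## Preprocessing

1. **Binning** — a read belongs to the bin containing its start
   coordinate (0-based half-open everywhere); at 75 bp reads and 1 Mb
   bins the start-vs-midpoint distinction is immaterial.  Reads on
   unknown chromosomes or beyond the last full bin are tallied and
   reported, not errors.
2. **Mappability** — counts are divided by per-bin mappability; bins
   below `min_mappability = 0.75` are masked instead of corrected (the
   paper-style self-alignment tracks do not say where to stop trusting
   the division; 0.75 is our choice).  Totals are not rescaled here.
3. **GC correction** — usable bins are grouped into GC intervals of
   width 0.1 %, interval mean depths are LOESS-smoothed (span 0.3,
   intervals weighted by bin count) and each bin is shifted
   **additively** by `median depth − loess(GC_i)`; one global factor
   then restores the exact input total.  The additive form follows the
   described correction ("difference between median and fitted depth");
   a multiplicative ratio-to-fit variant would not match it.  Note a
   side effect quantified in the analysis scripts: because the LOESS is
   fit on noisy interval means, the correction absorbs a small part of
   the *random* bin noise (first-order variance drops by roughly 10 %
   on bias-only simulations).  The correction is skipped with a warning
   below 100 usable bins or 3 populated intervals.
4. **Median normalization** — ratios are values divided by the median
   of usable bins, putting the diploid level at 1.0 as long as most of
   the genome is diploid.  `N`, the pre-normalization mean of usable
   bins, is recorded for the 1/N floor and the calling model.

Masking is hereditary: once masked, a bin is excluded from every later
statistic, difference and segment mean.

## Segmentation (CBS)

Circular binary segmentation with the classical arc t statistic: for an
interval of n bins the statistic is the maximum over arcs `[i, j)` of
the pooled two-sample t between arc and complement.  Significance is
assessed by permutation (default 1,000 permutations per interval,
α = 0.01); significant intervals are split at the best arc (ternary for
interior arcs, binary at an end) and the pieces recursed.  Implementation
notes:

* `min.width = 2`: arcs and every resulting edge piece must hold at
  least 2 bins, so single-bin outliers can never become segments.
* Ties in the statistic break to the smallest `(i, j)`; with a fixed
  permutation seed the segmentation is fully deterministic.
* Permutations are evaluated in vectorized chunks with early stopping:
  a test aborts as soon as enough exceedances have accrued that
  p > α is certain, which leaves the accept/reject decision identical
  to running all permutations while making flat chromosomes cheap
  (a full hg19 replicate segments in ~1 s).
* No "undo"/merge pass and no outlier smoothing: neither is part of the
  described analysis, and both would change the detection operating
  point silently.
* Segmentation is per chromosome (whole chromosomes, not arms) and a
  whole-chromosome aberration (the X monosomy) therefore surfaces as a
  single unsplit segment whose *mean*, not boundary structure, carries
  the signal.

### Detection limit under calibrated noise

The permutation null of the max arc t statistic has a heavy right tail
(small arcs with accidentally low within-arc variance), with 99th
percentile ≈ 5.6 for chromosomes of 90–140 bins.  A 3-bin single-copy
loss in noise of per-bin SD ≈ 28 % (the SurePlex-3-cell calibration)
yields observed max-T ≈ 3.5–4, so sub-4-bin events sit *below* the CBS
detection limit at this noise level: in the replicate study the 72, 45
and 13 Mb deletions and the X monosomy are detected essentially always,
the 3 Mb chr16q deletion usually, and the straddled 2.5 Mb chr9
deletion and 3-bin chr13 duplication rarely.  Mean sensitivity on the
seven-region fixture is therefore ≈ 0.70 under this preset, with
near-perfect PPV.  This is a genuine property of permutation-CBS at
α = 0.01 on iid bias of that magnitude — the detection claims one can
make at v ≈ 0.077 depend strongly on how much of the bias is removable
structure (GC, mappability, recurrent artifacts) rather than iid noise,
and the generator deliberately models the conservative iid case.

## Calling

Three negative-binomial components (monosomic / diploid / trisomic)
with means N/2, N, 3N/2, priors 0.05 / 0.90 / 0.05 and common
overdispersion `variance = d·mean`, d = 5.  The parameterization makes
d → 1 the Poisson limit (NB size `r = mean/(d−1)`, `p = 1/d`); the
alternative reading of "overdispersion 5" as the NB size parameter
would make larger values *less* dispersed, which contradicts its use as
a noise knob.  The thresholds are the integer counts (converted to
ratio units) where adjacent prior-weighted mass functions cross between
their modes — the minimal-misclassification boundaries, our reading of
"maximally separated peaks".  At N = 4000 and d = 5 these sit at ratio
≈ 0.727 and ≈ 1.249.  Because the component SD in ratio units is
√(d/N), thresholds drift mildly with depth (≈ 0.69 at N = 1000); they
are *not* exactly depth-invariant.

Segments beyond a threshold become calls with `copy number =
2 · seg_mean` (diploid-majority assumption) and `log2(seg_mean)`; the
exact logarithm is reported, so a clean trisomy sits at log2(1.5) ≈
0.585, not at the 0.5 sometimes quoted as the theoretical gain level.
Calls are threshold-based, never rounding-based; the rounded copy
number is reported alongside.  The X chromosome is treated as
diploid-expected (female line); a haploid-expected option covers male
samples.

## Noise statistic

The mean-scaled first-order variance

    v = Σ (y_i − y_{i−1})² / (2 · n_diffs),   y = counts / mean

with differences only between adjacent usable bins of the same
chromosome.  The /2 makes v an unbiased estimate of the marginal
variance for iid noise, so pure Poisson sampling gives exactly the 1/N
floor and `excess = v − 1/N` isolates the handling/amplification
contribution.  Unlike the global variance, v is nearly immune to true
CNAs — a step contributes one squared difference, O(1/n) — though
mean-scaling over a genome with ~10 % single-copy content still
inflates v by ~10 % relative to a flat genome.  Group comparisons use
Welch's t on replicate v values (the original comparison's test is
unspecified beyond "t-test"), with an exact degenerate path when both
groups are constant.

## Evaluation

≥ 1 bp direction-matched overlap scores a truth region as detected
(configurable to reciprocal overlap); multiple overlapping calls count
once.  Unmatched calls ≥ 3 Mb are false positives; smaller ones are
reported separately since the stated resolution of the 1 Mb design is
3 Mb.  The 2.5 Mb chr9 deletion stays in the truth set and is expected
to be *called* at 3 Mb granularity when detected.

## Problem sizes and defaults used by the shipped studies

Noise calibration runs use 25 replicates of 2,878 usable bins at
N = 4000; the sensitivity study uses 25 replicates of the full
3,030-bin grid; the analysis scripts use 10 replicates per preset.
These sizes put the Monte-Carlo SE of each reported mean well below the
effect sizes discussed, while keeping any single study in the
tens-of-seconds range.

## Known limitations

* The generator models bias as stationary log-normal (optionally AR(1));
  real WGA bias is heavy-tailed, partly recurrent across samples, and
  correlated with sequence features beyond GC — so passing tests
  demonstrate correctness of the pipeline's statistics, not real-data
  sensitivity, and real profiles may segment better (removable
  structure) or worse (outliers) than the calibrated analogue.
* No FASTQ-level simulation, no alignment errors, no allele-specific
  signal (no BAF at 0.1X), no recurrent-artifact blacklisting.
* CBS power for ≤ 3-bin events at v ≳ 0.08 is intrinsically poor (see
  the detection-limit note above); a smoothing/undo variant or a
  likelihood segmenter would trade false positives for small-event
  power but is out of scope here.
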