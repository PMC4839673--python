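# Methods

This note documents the statistical model behind `hybridcn`, the defaults
that matter, the synthetic study conditions used by the test suite and
`scripts/acceptance.py`, and the numerical choices made where the design
was genuinely open.

## Model

Read depth in hybrid-capture sequencing is treated as a noisy, biased
observation of the underlying copy number. For a bin *b* in a sample with
tumor-cell fraction (purity) *p* and normal ploidy *P*:

    depth_b ∝ (p · cn_b / P + (1 − p)) · 2^{β_GC(gc_b) + β_rep(rm_b) + β_dens(d_b) + ε_b}

where the β terms are sample-specific smooth bias functions of the bin's
GC fraction, repeat-masked fraction and target-density statistic, and ε_b
collects bin-specific capture efficiency and sampling noise. The pipeline
estimates `log2(p·cn/P + 1 − p)` per bin by:

1. log2-transforming mean per-base depth and median-centering over
   autosomes (log2 of empty bins is floored via a pseudo-depth of 0.01
   reads/base so bin sets stay aligned across samples);
2. removing each β by rolling-median detrending (below);
3. subtracting a reference profile of expected log2 depth built from
   pooled controls, which removes the shared part of ε;
4. median-centering the resulting log2 ratios.

Segmentation then fits a piecewise-constant model to the weighted ratios,
and calling inverts the purity mixture and rounds to integer copy number.

## Bias covariates

**GC fraction** is computed over the bin's exact footprint, on non-N bases
(an all-N bin records the neutral value 0.5). **Repeat fraction** is the
soft-masked (lowercase) proportion of the bin, following the UCSC
RepeatMasker convention.

**Target density** models two capture-edge effects in one statistic: depth
lost at a bait's "shoulders" and depth gained from the overlapping
"flanks" of close neighbors. Capture efficiency of a bait `[c, d)` is
modeled as a trapezoid: zero at distance f outside each edge, rising
linearly to full at f inside (default f = 300 bp, on the order of a
sequence-fragment overhang; CLI flag `--flank`). The statistic for a bin
is the exact integral of its own profile plus all neighbor profiles over
the bin, normalized by bin length, minus 1. For an isolated bin of size
s ≥ 2f this gives −f/(2s): negative, more so for small baits, increasing
toward 0 with size, and strictly increased by nearby neighbors. Only the
statistic's monotone relation to the true depth bias matters, since the
correction is rank-based; no cross-implementation numeric equality is
claimed for this statistic.

### Correction scope

GC correction is applied to on-target and off-target bins independently
(their capture chemistry differs); the repeat correction to off-target
bins only — on-target bins are exonic, rarely overlap repeats, and when
they do they tend to be entirely covered, leaving no trend to fit; the
density correction to on-target bins only, since it models bait geometry.
Order: GC first, then repeat/density.

### Trend estimation

Bins are sorted by the covariate; the trend is a centered rolling median
of the log2 values in that order and is subtracted. Windows are a
fraction 0.1 of the bin set (minimum 50 bins); edges use symmetric window
shrinkage (position i uses `[i−k, i+k]`, k = min(half-window, i, n−1−i)),
which makes the median track a monotone sequence exactly — detrending a
noiseless monotone trend leaves an exactly flat residual. A constant
covariate degenerates to global median centering, as does a window
fraction of 1.

For the repeat and density corrections the window is widened 3× and the
fitted trend is projected onto monotone functions (isotonic regression,
direction chosen by fit quality). Rationale: these two biases are
monotone in their covariate by construction, so the projection removes
non-monotone wander of the estimate; the GC trend is unimodal and keeps
the narrower, unconstrained window. LOWESS and a Kaiser-window moving
average are available as alternate smoothers (`SmootherSpec.method`); all
three agree within 0.05 log2 units on smooth trends.

## Reference (panel of normals)

Each control is bias-corrected, then per bin the reference stores the mean
corrected log2 depth and a dispersion ("spread") across controls —
normal-scaled MAD by default; standard deviation and IQR are registered
alternatives. Bins where at least half the controls fall below 0.05
reads/base keep their row but receive an infinite sentinel spread, so
downstream bin sets stay aligned while normalization drops them. With no
controls a flat reference (log2 0, spread 0) is used. A "male reference"
stores the X chromosome at half the autosomal expectation (log2 −1); when
the controls are diploid-X their X values are shifted accordingly, so
pooled and flat references agree on the convention.

## Weights and balancing

Bin weight is the product of three factors in (0, 1]: size
(`min(1, len/median_len)` within the bin set), centrality
(`2^−|ref log2|`, requires ≥1 control), and spread
(`1/(1 + (spread/0.25)²)`, requires >1 control). The forms are smooth,
bounded and monotone; the constants set the soft scale at which each
factor starts to matter. Finally the more variable of the on-/off-target
sets — variability measured as the scaled MAD of successive differences of
genomically ordered log2, robust to true copy-number steps — has its
weights multiplied by the ratio of the smaller to the larger variability.

## Segmentation

**CBS** is implemented directly: per chromosome, the arc (i, j) maximizing
the weighted two-sample t statistic between the arc and its complement on
the circularized bin sequence is found by exhaustive O(n²) scan over
partial sums; the split is accepted if fewer than α·n_perm of n_perm
within-segment permutations reach the observed statistic (default
α = 0.01, n_perm = 100, seeded generator, bit-reproducible), then
recursion proceeds on the fragments (minimum segment: 3 bins). No "undo"
pruning is applied in this version. **Haar** segmentation convolves the
log2 sequence with step kernels at dyadic scales, normalizes by a robust
noise estimate (scaled MAD of successive differences / √2), keeps local
maxima passing a Benjamini–Hochberg threshold (default FDR 0.001) on
two-sided normal tail probabilities, and merges detections across scales
keeping the finest localization.

An optional pre-filter zeroes the weight of outlier bins: within a rolling
window (default 50 bins), deviations beyond 4× the 95th percentile of
|log2 − window median| are excluded from fitting but retained in the
output. The percentile uses lower interpolation so a lone extreme value
cannot raise its own window's threshold. Zero-weight bins are excluded
from change-point fitting and segment means but counted into segment
spans.

Segment log2 is the weighted mean of member bins; segments partition the
segmented bins exactly.

## Calling

Purity rescaling inverts the two-population mixture:
`r_tumor = (2^log2 − (1 − p)) / p`, floored at 2^−5 so homozygous
deletions stay representable. Re-centering offers median, mean, mode
(Gaussian KDE with Silverman bandwidth, grid argmax) and Tukey biweight
location, each weighted by segment bin counts. Integer calls are
`max(0, round(P · 2^log2))`, or, with explicit ascending thresholds, the
number of thresholds exceeded. The FISH helper converts mean nuclear
signal counts to log2 ratios as `log2(count) − log2(ploidy)`.

## Synthetic study conditions

The default cohort (`SimConfig()`): 2 chromosomes × 30 Mb, 150 genes × 5
exons (≈1,270 on-target bins of ≈270 bp after subdivision, ≈380 off-target
bins of ≈150 kb), 4 pooled controls and 4 tumors, each tumor with a 6 Mb
gain (cn 4) and a 6 Mb single-copy loss placed at seeded positions
(event span scales as 20% of the chromosome, capped at 6 Mb). Depths:
300× on-target, 2× off-target. Noise and biases, all in log2 units:

- multiplicative sampling noise, sd 0.15 — the Poisson-equivalent noise of
  a few hundred reads per bin;
- a per-bin capture-efficiency effect shared by all samples of a cohort,
  sd 0.25 — the component only reference normalization can remove; its
  size yields self-normalized residual noise of ≈0.15 log2, matching
  residual MADs reported for real hybrid-capture data;
- a sigmoid GC trend of amplitude 0.8 (≈±0.4 log2 across the GC range), a
  density bias of 1.2 × the density statistic, and a repeat bias of −1.2 ×
  the repeat fraction (≈1 log2 span) — magnitudes consistent with
  published per-sample bias trendlines.

GC is spatially smooth (sinusoidal isochore-like field, wavelength 7 Mb,
per-bin jitter 0.03); repeat fraction is ≈0 on exonic targets and
iid-variable around the genome-wide repeat density (0.3 ± 0.2, clipped)
on off-target bins, as real per-bin RepeatMasker fractions are dominated
by bin-to-bin variation. Truth tables store the exact integer cn and
mixture log2 per bin; no estimated quantity enters them.

What the generator does **not** emulate: real read sequences and their
error profiles, mappability structure, FFPE artifacts, subclonal
heterogeneity, and sex-chromosome dosage. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
noise model, not performance on any particular clinical panel.

The step-wise evaluation (`evaluate_steps`) mirrors the pipeline:
deviations of each bin's log2 estimate from truth are summarized per
tumor and bin set at four stages (raw, +GC, +density/repeat, +reference).
Deviation is measured around the per-set median of (estimate − truth) —
a dispersion — because median-based centering interacts with the skewed
repeat term: removing a skewed bias component shifts a set's level, which
centering absorbs in the full pipeline. At desk-scale bin counts the
per-sample improvement of the density/repeat step is small relative to
its finite-sample noise; the injected amplitudes above are the smallest
at which each correction's effect is individually resolvable per sample.

## Problem sizes used in tests and the acceptance script

Oracle checks: 200 (tests) / 100 (script) random tiny BAMs of ≤50 reads
against a naive per-base pileup, exact equality; 500 random target sets
against a per-bp interval-partition oracle. Bias removal runs on a larger
simulated panel (6 chromosomes × 50 Mb, ≈7,000 bins) where rank
correlations are well resolved. Segmentation calibration uses 100
replicates of a 200-bin step signal (Δlog2 = 1, sd 0.2) plus 100
pure-noise chromosomes per backend. The full suite runs in well under a
minute on one CPU.

## Known limitations

- CBS has no undo/prune step; very long chromosomes use an O(n²) scan per
  split, adequate for bin counts in the tens of thousands.
- The reference assumes all controls share the exact bin set; there is no
  re-binning or lift-over.
- No Y-chromosome model and no coverage-based sex inference; sex-chromosome
  ploidy is supplied by the caller.
- Off-target depth at very low coverage (<1 read/bin) is dominated by the
  log2 floor; such panels should use larger antitarget bins
  (`suggest_antitarget_size`).
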