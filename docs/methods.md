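# Methods

This note records the models, conventions and numerical choices behind
`ffpesig`, in the order the pipeline runs them, and what the synthetic
cohorts do and do not establish about real data.

## Detection p-values and %P-call

Vendor software computes "present" calls against built-in negative
controls but does not document its exact formula.  We use the add-one
empirical rank

    p(cell) = (1 + #{control signals in the sample >= cell signal}) / (1 + n_controls),

one-sided with the controls as the null distribution.  It is exact,
oracle-checkable, lies in (0, 1], and is monotone non-increasing in
signal within a sample.  Because it is a rank statistic, %P-call — the
fraction of non-control genes with p below `detection_alpha` — is
invariant to any monotone transform applied jointly to a sample's
signals.  `detection_alpha` defaults to 0.05 and is configurable; it is
a dialect of the vendor computation, not a reproduction of it.  At
least 20 flagged controls are required; fewer makes the rank too coarse
to support a 5% call.

The exclusion rule is *strict below*: a profile with %P-call exactly at
the threshold (default 0.20) is retained.  `suggest_pcall_threshold` is
advisory only: it scans candidate cuts for the largest drop in mean
median-array correlation between the two sides, after removing a linear
trend so a smooth decline is not mistaken for a change-point (a cut is
reported only when the detrended drop exceeds twice its pooled standard
error; otherwise the default is returned with a warning).

Median-array correlation is computed on the log2 scale over non-control
genes.  Controls carry no biology, and raw-scale skew would let a few
bright probes dominate Pearson r.  Undetected cells stay in the
computation — their floored signal is data.  Zero-variance profiles get
NaN with a warning rather than an error.

## qspline normalization

The reference profile is the per-gene geometric mean across samples (or
an explicit vector).  Each sample is summarized at 14 anchor
probabilities evenly spaced on [0.02, 0.98]; anchor quantiles are taken
at the *nearest order statistic*, so anchors are actual data values.
The map from sample anchors to reference anchors is a monotone
piecewise-cubic interpolant (PCHIP) after projecting the anchor images
onto the nearest nondecreasing sequence (pool-adjacent-violators);
outside the anchor range it continues linearly with the boundary slope.

A natural cubic spline through the anchors can locally invert even when
the anchors themselves are increasing; the monotone cubic makes rank
preservation a structural guarantee rather than a post-hoc fix, which
downstream rank-based QC requires.  Consequences verified by tests:
identical arrays map to themselves (1e-6), anchored output quantiles
equal reference quantiles to machine precision, and within-sample order
statistics are preserved exactly.  Values must be strictly positive
(the geometric mean needs logs); callers floor at a tiny epsilon first.
The pipeline normalizes *after* the %P-call filter, so the reference is
built from QC-passing samples only; profile order (filter before
normalize) is a documented choice, not an external requirement.

## Digital-count normalization

Counts are transformed as `log2(count + 1)` — the +1 offset admits
zeros — and each sample is shifted by the difference between the grand
mean of per-sample control log2 means and its own control log2 mean.
Control geometric means are therefore identical across samples exactly,
by construction, on the offset scale.  Re-centering to the grand mean
rather than to zero keeps absolute expression levels interpretable.

## Nearest template prediction

Templates assign +w to a class's up-markers, −w to its down-markers and
0 to other classes' markers, over the union of signature genes laid out
in a canonical order (classes sorted, genes sorted within class), so
the template set is independent of signature entry order.

NTP is single-sample, so gene-wise z-scoring against a cohort is
unavailable.  We standardize *within* the sample — subtract the profile
mean, divide by the profile standard deviation, over non-control
genes — before extracting signature genes.  This keeps the classifier
strictly single-sample and makes the call invariant to affine rescaling
of the profile.

The null distribution draws `n_resamples` gene sets of signature size
uniformly *without replacement* from the assayed non-control panel and
applies the template sign/weight pattern to each random set;
the confidence p-value is the add-one fraction of null distances at or
below the observed minimum-over-templates distance.  Drawing from the
whole panel (not signature genes only) matches the question the
p-value answers: how unusual is this proximity relative to arbitrary
gene sets of the same size.  p is super-uniform under exchangeable
genes; the suite verifies calibration at the nominal 5% on class-free
profiles and agreement with exhaustive enumeration on a panel small
enough to enumerate.  Defaults: 1000 resamples (p resolution ~0.001),
confidence threshold 0.05 strict (`p = 0.05` is *not* confident).
Per-sample seeds are `master_seed + sample_index`, so any single call
reproduces in isolation.  Distance ties between templates resolve to
the first class in order and set `tie_flag`.  Signature genes missing
from the panel are dropped with a warning up to 10%; beyond that the
prediction is refused as unreliable.  Benjamini–Hochberg FDR across a
cohort is delegated to statsmodels and cross-checked against an
independent step-up implementation in the tests.

## Concordance

Paired predictions are matched by sample id, cross-tabulated in
signature class order (absent classes padded with zero rows/columns),
and summarized as percent agreement — diagonal over total, rounded
half-up to the integer percent, the convention of clinical concordance
reporting (e.g. 55/64 → 86%, 36/37 → 97%).  The unrounded value is
returned alongside.  The confident subset restricts to pairs confident
in *both* arms before tabulating; an empty subset reports an explicit
zero count rather than an undefined percentage.  Cohen's kappa is
available as an auxiliary chance-corrected statistic.

## The synthetic cohort generator

The generator's defaults are the study conditions for every
statistical test in the suite.

**Fresh-cut arm.**  Per-gene baseline log2 intensities are
Normal(11, 4) — a wide dynamic range typical of genome-scale arrays;
class effects shift each marker by ±`effect_size` (default 1.5 log2
units, alternating up/down markers within each class's block of 30);
per-cell noise is Normal(0, 0.5).  Raw intensities are `2^x` floored at
per-cell background draws; negative controls (200 probes) are pure
background, log-normal moment-matched to mean 100, sd 30 on the raw
scale.

**Degradation model.**  Degradation sites scatter essentially at
random along transcripts, so the probe-spanning fragment of a
transcript with effective length L (kb, log-normal with median 1 kb,
log-sd 0.5) survives with probability `exp(−severity × L)`.  Each
cell's surviving fraction is Binomial(200, p)/200 — an intensity
aggregates many molecules — and the archived arm's signal is further
divided by `attenuation` (default 40, the assayable-material loss
factor), then floored at draws resampled from the sample's own
controls.  Control probes are background and pass through unchanged.
With severity 0 and attenuation 1 the input is returned unchanged: an
undegraded aliquot is the same measurement, so no new background is
drawn (the one discontinuity in the model, documented here).

**Severity heterogeneity.**  Per-sample severities are gamma with mean
`severity` (default 2.4 /kb) and sd `severity_spread` (default 1.2).
These defaults were calibrated once so the shipped configuration
reproduces the archival-cohort regime: mean fresh-cut %P-call inside
70–90%, mean archived %P-call inside 10–60%, mean archived median-array
correlation inside 0.4–0.9, and a visibly wider archived correlation
range than fresh-cut.

**Technical replicates.**  Replicates re-assay one extract, so they
share the degraded signal and differ only by multiplicative measurement
noise `2^Normal(0, tech_sd)` per cell.  `tech_sd = 0.25` places the
replicate R² of a typical archived sample (the one at the cohort's
median severity) at ≈ 0.91, the reproducibility regime of
intermediate-to-poor quality FFPE arrays.

**Digital-count panel.**  Signature genes plus 400 unrelated panel
genes (so resampling confidence has a background to draw from) and 20
control probes.  Counts are negative-binomial (dispersion 20) around
`scaling × 2^(base + class effect)` with log-normal per-sample scaling
factors (log2-sd 0.25, the library-size analogue); controls are Poisson
around `scaling × 2^10`.

**Seed policy.**  One master seed; fixed substream offsets for
structure, fresh-cut noise, degradation and counts, so each arm is
independently reproducible.

**What the simulations do not show.**  The generator has no probe
sequence effects, no batch or chip artifacts, no spatial structure, and
its degradation acts independently per cell given severity — real
archived sections correlate damage across transcripts and blocks.
Passing tests establish that the pipeline's statistics behave as
designed under a faithful statistical caricature of archival cohorts;
they do not certify performance on any particular real platform.

## Problem sizes and determinism

Cohort-level checks run at the default scale (100 samples × 8000 gene
probes + 200 controls); calibration of the null confident-call rate
uses 1000 class-free profiles at 1000 resamples each; trend and
recovery properties use reduced cohorts (≈1200–1500 genes, 40–60
samples) chosen to keep the full suite within a few minutes while
leaving the statistics well-resolved.  Every stochastic test and the
acceptance script are fully determined by explicit seeds.

## Known limitations

- The detection p-value and present-call alpha are documented dialects,
  not reproductions of any vendor's proprietary computation.
- The qspline variant here anchors at nearest order statistics and
  enforces monotonicity; implementations differing in anchor placement
  or tail handling will differ in the extreme quantiles.
- The attenuation factor is a free parameter: the mapping from
  replicate R² to assayable-material loss depends on assay-development
  calibrations not reproducible from summary statistics, so 40 is a
  default, not an estimate.
- NTP standardization and resampling counts are package choices; other
  NTP implementations may standardize differently and will produce
  numerically different (though similarly calibrated) p-values.
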