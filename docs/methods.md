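# Methods

## Problem setting and model

The package evaluates univariate time-series features of bipolar fly-LFP
channels as classifiers of conscious level.  Each hypothesis is local: one
feature at one channel either separates wakeful from unconscious epochs
across flies (classification) or changes in a consistent direction within
flies (consistency).  All model fitting is confined to a discovery set of
flies; evaluation datasets only ever see frozen thresholds, directions and
scaling parameters, which is what makes the generalization claims honest.

## Synthetic data generator

The generator stands in for the recordings: it reproduces the *statistical
structure* the analysis depends on, not fly physiology.

Signal model: each channel-epoch is a stationary AR(1) (discrete
Ornstein–Uhlenbeck) process, x_t = φ x_{t−1} + ε_t with
φ = exp(−Δt/τ), Δt = 1 ms at the 1,000 Hz default rate, innovations scaled
so the stationary SD is σ, and x_0 drawn from the stationary law.  Its
lag-k autocorrelation is φ^k, so τ is a directly interpretable
autocorrelation time constant.  AR(1) is the simplest process with a
tunable correlation timescale; richer spectra (oscillations, 1/f slopes)
are deliberately out of scope, so passing tests say nothing about features
that would only be exercised by such structure.

Defaults are the study conditions: 13 discovery and 12 evaluation flies, 8
epochs of 2.25 s per fly and condition, 16 electrodes (15 bipolar
channels), τ_wake = 30 ms vs τ_unconscious = 8 ms, σ_wake = 1.5 vs
σ_unconscious = 1.0.  The wake/unconscious variance ratio and the
evaluation batch gain are free parameters, not estimates; 1.5 and 3.0 were
chosen once as a clearly-resolvable condition effect and a clearly
range-breaking batch shift, respectively.

Structure on top of the AR(1) core:

- **Channel effect profile** w_c ∈ [0, 1]: wake parameters at channel c
  are the unconscious ones plus w_c times the difference, so w_c = 0 makes
  the two conditions statistically identical there.  The default profile
  tapers linearly from 1 at the deepest channel to 0 at the shallowest,
  giving every study a built-in null channel for false-positive
  calibration.
- **Exact channel-level ground truth**: electrode e is constructed as a
  shared base AR(1) plus the cumulative sum of the per-channel processes
  from e upward, so bipolar differencing recovers the designed channel
  processes exactly rather than approximately.
- **Fly offsets**: additive DC per (fly, electrode), constant across that
  fly's epochs (SD 0.5).  These are removed by epoch mean subtraction and
  exist to exercise preprocessing; feature-level fly heterogeneity for the
  consistency-vs-accuracy contrast is constructed directly in tests.
- **Batch effects**: per-dataset multiplicative gain and optional
  Butterworth low-pass.  An additive voltage shift would be nulled by mean
  subtraction, so the dataset-level "range shift" failure mode is realized
  as gain, which moves every amplitude-family feature while leaving
  scale-invariant features (autocorrelation, permutation entropy) alone.
- **Line noise**: a sinusoid per electrode and epoch with random phase and
  ±50% amplitude jitter (default 50 Hz, amplitude 0.5).  Phases differ
  across electrodes so the contamination survives bipolar re-referencing;
  a common-mode sinusoid would vanish and leave the cleaning stage
  untestable on pipeline data.
- **Randomness**: every fly has an independent child stream keyed by
  (master seed, dataset index, fly index), so enlarging a study never
  changes existing flies' samples.

## Preprocessing

Order of operations: bipolar re-reference (deeper minus shallower; the
unstated sign convention only flips feature directions, which are learned
from data), epoch segmentation from sample 0 with the sub-epoch tail
discarded, per-epoch mean subtraction, then line-noise removal, then a
final re-centering (the removed sinusoid spans a non-integer number of
cycles, so its subtraction shifts the mean by a small amount).

Line-noise removal is a Thomson multitaper harmonic regression: with DPSS
tapers h_k (time-bandwidth 5, 9 tapers), the complex line amplitude is
estimated as ĉ = 2 Σ_k U_k J_k / Σ_k U_k², where J_k is the tapered
eigencoefficient at the line frequency and U_k the taper sum, and
Re(ĉ e^{iωt}) is subtracted.  The estimator is linear in the data, so the
whole epoch stack is cleaned with one matrix product.  It is not exactly
idempotent (negative-frequency leakage over non-integer cycles leaves a
residual about 0.2% of the line amplitude); the contract is attenuation
≥ 20 dB of an injected sinusoid with < 5% RMS distortion of clean noise,
not bit-equivalence with any reference tool.  The quantitative stand-in
for a visual spectrum check is `line_qc_ok`: post-cleaning Welch power at
the line frequency within 6 dB of the neighboring-frequency median.

## Feature definitions and conventions

Sample SD uses the N−1 denominator everywhere; the autocorrelation
estimator uses the biased (N) normalization, which is standard and keeps
high-lag estimates stable.  `AC_k` means a lag of k samples (= k ms at
1,000 Hz).  Features return NaN when undefined (constant input for
AC/StatAv/SampEn/ApEn, zero power for spectral log/edge outputs); by
convention permutation entropy and LZ76 complexity of a constant series
are 0.  Welch "rect" spectra use a rectangular window with
nperseg = min(N, 1024) and 50% overlap; the "fft" variants use a plain
periodogram.  `SP_Summaries_welch_rect_logarea_2_1` is the natural log of
the integrated PSD over the lower half of [0, Nyquist]; `area_5_1` is the
lowest fifth.  These band conventions, and reading `minr13` as "report the
dimension estimate at scale index 13", are reasoned reconstructions of
toolbox-internal naming; both are parameters, so alternates can be swapped
in.

The correlation dimension embeds the series with delay equal to the first
zero-crossing of the ACF (NaN if none occurs within N/2 lags), dimension
5, evaluates the correlation sum at 50 log-spaced radii spanning the
pairwise-distance range, and reports the local slope of log C(r) vs log r
at the requested scale.  Local slopes are fit by least squares over a ±2
scale window because two-point gradients are unusable where C(r) is a
step function; embedded points are capped at 1,000 by strided subsampling
to bound the O(n²) distance computation.

Sample/approximate entropy use m = 2 and r = 0.2·SD with Chebyshev
distance; SampEn excludes self-matches and returns NaN when no templates
match.  LZ76 complexity binarizes at the median, counts phrases by the
Kaspar–Schuster scheme and normalizes by c·log₂(N)/N.

Validity filtering reproduces the discovery-only rule: a feature is
invalid at a channel when it returns NaN for *all* discovery epochs there,
or a constant across all of them; evaluation data never influence the
mask.  The robust sigmoid maps v ↦ 1/(1 + exp(−(v − m)/(1.35 q))) with m
and q the median and IQR of the *reference* (discovery) values, followed
by min–max rescaling over the reference's transformed range; q = 0 yields
flagged all-NaN output.

## Classification and inference

Medians are order statistics, so ±∞ feature values participate without
special-casing; a mixed ±∞ even-count midpoint is NaN and the feature is
skipped as untrainable.  Tie rules are deterministic: a value exactly on
the threshold is classified unconscious, and equal class medians give
direction −1 (the literal "otherwise" of the labeling rule) with the
classifier flagged degenerate.  NaN epoch values count as misclassified
rather than being dropped, so accuracies stay comparable across features.

The permutation null labels each epoch independently with probability ½
and records the agreement fraction; 7,702 repetitions (the size of the
full feature library the design budgeted for) give a ±0.5% Monte-Carlo
band on the 50% null mean.  p-values use the +1 correction, so the
smallest attainable p is 1/(reps+1).  FDR is Benjamini–Hochberg step-up
within each channel (features at one channel are positively dependent —
e.g., neighboring AC lags — and BH is valid under positive dependency);
the implementation delegates to statsmodels and is tested against an
explicit step-up enumeration.

Batch normalization z-scores evaluation values per dataset and channel
(non-finite values ignored in the moments, passed through unchanged) and
back-transforms with the discovery moments.  The consistency null draws,
for each wake epoch, a proportion uniformly from that fly's achievable
discrete set {0, 1/n_u, …, 1} — matching an equal-probability random
assignment of below-counts — rather than a continuous uniform.

Consistency averages the per-wake-epoch proportions pooled over flies
(flies implicitly weighted by wake-epoch count); equal-fly weighting is an
option.  Ties count as not-below.

## Reported problem sizes

The end-to-end parameter-recovery check runs the generator's default study
(13 + 12 flies, 16 electrodes, 8 epochs per condition) with a 12-feature
registry drawn from the cheap families (autocorrelation, variance,
stationarity, Poincaré, spectral, permutation entropy); the
correlation-dimension and sample-entropy features are validated on single
series, where their oracles (known-dimension embeddings, brute-force
template counting) are exact.  Monte-Carlo checks of generator statistics
use 100–200 epochs, which puts the standard error of a mean lag-30
autocorrelation near 0.004 against the ±0.05 assertion band.

## Known limitations

The generator's AR(1) spectrum is monotone; oscillatory or 1/f structure,
artifacts, and non-stationarity within epochs are absent, so features
whose discriminative power would come from those properties are only
contract-tested, not validated for power.  Consistency's robustness claim
covers monotone per-fly distortions only.  The clustering stage treats
non-estimable feature pairs as maximally distant, which can inflate
cluster counts for very sparse features.
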