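# flywake

Which univariate time-series features of a brain signal distinguish
wakefulness from general anesthesia and sleep — and keep doing so in
recordings they were never trained on?  `flywake` implements the full
analysis pipeline for asking that question of multi-channel fly local field
potential (LFP) data: a library of named univariate features, per-feature
nearest-median classifiers with leave-one-fly-out and cross-dataset
evaluation, permutation nulls with per-channel false-discovery-rate
control, and a rank-based within-fly effect-direction consistency
statistic.  A synthetic LFP generator with the same fly/dataset/condition
structure makes every stage testable end to end without any recordings.

The package is aimed at computational neuroscientists studying markers of
conscious level, and more generally at anyone evaluating whether
single-feature classifiers of a physiological state generalize across
individuals and recording batches.

## The methods in brief

**Data model.** Recordings come from linear 16-electrode probes sampled at
1,000 Hz.  Adjacent electrodes are subtracted (bipolar re-referencing) to
give 15 channels, channel 1 deepest; signals are cut into 2.25 s epochs
(8 per fly per condition from an 18 s rest period), mean-subtracted, and
cleaned of mains noise with a multitaper harmonic regression (9 DPSS
tapers, time-bandwidth 5).

**Features.** Each epoch × channel yields one value per registered feature:
autocorrelation at fixed lags `AC_k` (the biased estimator
r_k = Σ(x_t−x̄)(x_{t+k}−x̄)/Σ(x_t−x̄)²), mean-stationarity `StatAvl250`
(SD of window means / global SD), distribution statistics (`rms`,
`standard_deviation`, standardized moments `DN_Moments_raw_k`),
Poincaré variabilities `MD_rawHRVmeas_SD1/SD2`, Welch/FFT band powers and
spectral edge frequencies (`SP_Summaries_*`), entropies and complexity
(`EN_SampEn`, `ApEn`, `EN_PermEn`, `EN_MS_LZcomplexity`), local-extrema
spread (`ST_LocalExtrema_n50_stdmax`), and a correlation dimension on a
delay embedding (`NL_BoxCorrDim_50_ac_5_minr13`).

**Classification.** For feature f at channel c, the classifier is a
threshold θ = (median_wake + median_unconscious)/2 over the discovery
training epochs plus a direction d = sign(median_wake −
median_unconscious); an epoch with value v is called wake iff
d·(v − θ) > 0.  Discovery performance is leave-one-fly-out
cross-validated; generalization applies discovery-trained classifiers to
independent datasets over every wake-like × unconscious-like condition
pair (balanced designs, so chance is exactly 50%), optionally after batch
normalization v′ = (v − m_eval)/s_eval · s_disc + m_disc.  Significance
comes from a random-classification permutation null (default 7,702
repetitions, p = (1 + #{null ≥ obs})/(reps + 1)) with Benjamini–Hochberg
FDR at q = 0.05 within each channel.

**Consistency.** For each wake epoch of each fly, the proportion of that
same fly's unconscious epochs lying below it (values first multiplied by
the discovery-derived direction label), averaged over all wake epochs and
flies: 1 means the effect direction is conserved for every within-fly
pairing, 0.5 is chance, 0 means it is reversed.  Being rank-based, the
statistic survives per-fly baseline shifts that destroy across-fly
classification.

**Synthetic studies.** Epochs are stationary AR(1) signals with
condition-dependent time constant (wake 30 ms vs unconscious 8 ms by
default, so wakeful signals carry autocorrelation ≈ 1/e at 30 ms lag) and
SD (1.5 vs 1.0), a per-channel effect-strength profile, per-fly baseline
offsets, dataset-level gain or low-pass batch effects, and line-noise
contamination.

## Worked example

`examples/03_classification.py` trains on 6 synthetic discovery flies and
evaluates on 5 flies "recorded" with a 3× amplitude batch shift:

```
leave-one-fly-out CV on discovery (channel 1):
  AC_30                  mean acc 0.99 (SD 0.03 over 6 folds)
  standard_deviation     mean acc 1.00 (SD 0.00 over 6 folds)
  StatAvl250             mean acc 0.88 (SD 0.06 over 6 folds)
  EN_PermEn              mean acc 0.69 (SD 0.15 over 6 folds)

evaluation dataset, channel 1 (batch gain 3x):
  AC_30                  raw acc 0.97 (sig=True)   normalized acc 0.97 (sig=True)
  standard_deviation     raw acc 0.50 (sig=False)   normalized acc 1.00 (sig=True)
  StatAvl250             raw acc 0.89 (sig=True)   normalized acc 0.89 (sig=True)
  EN_PermEn              raw acc 0.86 (sig=True)   normalized acc 0.86 (sig=True)
```

Both features separate the conditions perfectly within the discovery
flies, but the amplitude shift sends the raw `standard_deviation`
classifier to chance (0.50) in the new dataset while scale-invariant
`AC_30` generalizes untouched; normalizing the evaluation values to the
discovery mean and SD repairs the variance feature.  The other examples
cover the generator and ground-truth checks (`01`), feature extraction,
validity filtering and robust sigmoid scaling (`02`), and consistency plus
absolute-Spearman feature clustering (`04`).

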