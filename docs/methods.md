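# Methods

This note documents the models, estimators and design choices behind
`tftseg`, what the synthetic-data generator does and does not emulate,
and the numerical conventions that affect results.

## Signal model and preprocessing

The EEG is treated as a 14-channel, 128 Hz signal in microvolts on the
10/20 subset AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4.
Times are 0-based seconds; all intervals are half-open `[start, end)`.

**Band-pass.** 2–50 Hz, Butterworth of design order 8 applied
forward–backward (`sosfiltfilt`). The band covers the rhythms usually
linked to cognitive activity while excluding mains interference; the
zero-phase implementation is chosen so that filtering cannot shift
segment boundaries. The effective magnitude response is the squared
design response (≈25 dB down at 60 Hz).

**ICA.** Deflationary FastICA with unit-variance whitening, fixed seed,
full channel rank required, and at least 30 s of signal demanded for a
stable unmixing. The decomposition stores mixing, sources and channel
means so that `mixing @ sources + mean` reproduces the filtered input to
numerical precision — removal of nothing is exactly the identity.

**Artifact detection.** A reduced reimplementation of the ADJUST
feature set, computed per component:

* SAD — mean |anterior weight| − mean |posterior weight| (anterior =
  AF/F/FC rows by nomenclature);
* SED — |mean weight over {AF3, F7} − mean over {AF4, F8}|, the closest
  electrodes to the eyes in this montage;
* TK — temporal kurtosis of the source, averaged over 1 s epochs;
* MEV — max epoch variance / mean epoch variance;
* GDSF — largest deviation of an electrode weight from the
  exp(−distance)-weighted mean of the other electrodes.

Thresholds are set automatically per feature by a two-component
Gaussian-mixture split on the standardized values, with EM initialized
at the bulk (median) and the top value and a covariance floor
(`reg_covar = 0.01` on the standardized scale) so neither component can
collapse onto a single observation — on 14 data points unconstrained EM
otherwise produces degenerate fits. If the two fitted components are not
separated by at least one component standard deviation, the feature
yields no flags. Classes: blink = SAD & TK, vertical eye movement =
SAD & MEV, horizontal = SED & MEV, generic discontinuity = GDSF & MEV
(first match wins). A practical caveat: a smooth 0.3 s blink pulse has
only mildly elevated kurtosis inside 1 s epochs, so a blink component is
occasionally classed as a vertical eye movement; it is flagged and
removed either way, which is what matters downstream.

## TFT segmentation

**Tensor.** Magnitude-squared STFT (Hann taper, PSD scaling) per
channel, cropped to 2–50 Hz. Window 2 s / hop 0.5 s: 0.5 Hz frequency
resolution at 128 Hz and boundary quantization of 0.5 s (4× oversampled
relative to the window). These are free parameters of the method.

**Features.** `log(power + 1e-12)` flattened over (frequency × channel),
each column z-scored over time. Standardization keeps any single
channel or band from dominating the clustering metric and makes the
segmentation exactly invariant to global amplitude rescaling of the
input. Note that z-scoring also fixes the global mean pairwise row
distance, so comparisons of temporal structure between recordings are
meaningful on the raw log-power matrix, not the standardized one.

**Constrained clustering.** Agglomerative merging restricted to
temporally adjacent clusters; merge cost is the Ward within-cluster
sum-of-squares increment n₁n₂/(n₁+n₂)·‖μ₁−μ₂‖² (average linkage
available as an option). Ties break toward the earliest left boundary,
making the procedure fully deterministic. Each cluster is one contiguous
interval — a TFT-epoch; the implementation does not let a cluster recur
in disjoint intervals. The cut is either a user-supplied k or chosen at
the largest ratio between successive merge heights, bounded by k_max
(default 10); perfectly uniform heights fall back to k = 1. Correctness
is checked against a from-scratch O(n³) reference and against
chain-connectivity Ward in scikit-learn.

## Entropy

What the entropy is "of" is a convention of this package: the pooled
standardized log-power feature values inside one temporal segment,
reported in nats. The estimator is the histogram plug-in
−Σ p̂ᵢ ln p̂ᵢ with the first-order bias correction +(M−1)/(2N) (M
occupied bins, N pooled values) and, for the differential reading, the
offset ln Δ for bin width Δ. Bin count defaults to ⌈√N⌉. Degenerate
inputs (zero range, or a segment whose rows are all identical) score 0.
Accuracy at the sizes used: ≤2% relative error on the Gaussian closed
form ½ln(2πeσ²) at N = 10⁵, ≤0.02 nats on a discrete uniform, and the
affine equivariance H(aX) = H(X) + ln|a| holds exactly because the bins
scale with the data range.

Sessions are split at the temporal midpoint (configurable fraction);
a segment is "early" if its midpoint precedes the split. Stage summaries
are mean ± SD (n−1) and a one-tailed Mann–Whitney U (early > late).

## Behavioral scoring and statistics

Scores are 100·hits/attempts; attempts = 0 yields a NaN marker rather
than 0 or an exception so longitudinal tables stay rectangular.
NASA-TLX weights come from the complete set of 15 pairwise choices
(weight = pairs won, Σ = 15); ratings live on the 21-point 0–100 scale
in steps of 5; overall = Σ(rᵢwᵢ)/15.

Mann–Whitney U: the stored statistic is U₁ = #pairs(x beats y), which
satisfies U(x, y) + U(y, x) = n₁n₂; reports print the SPSS-style
min(U₁, U₂). The p-value is exact by enumeration when the smaller group
has ≤8 observations and the pooled sample is tie-free, otherwise the
normal approximation with midrank tie correction and continuity
correction. The configured contrast set tests the hypothesized
directions: virtual > real improvement, low > high abstraction
trained-task gain, high > low abstraction opposite-task score, and
workload decreasing more under virtual training and high abstraction.
Under null cohorts the pooled empirical type-I error at α = 0.05 is
≈0.05 (checked over 1000 simulations).

## Synthetic data: what it emulates, what it does not

**EEG.** Each regime is Gaussian noise spectrally shaped to a target
one-sided PSD: a 1/f background (reference level at 10 Hz) plus
constant-PSD bands within 2–50 Hz, independent across channels, pieced
together in time. This gives exactly the structure the segmentation
stage assumes — piecewise-stationary band power — with controllable
contrast. Blinks are raised-cosine pulses (0.3 s) with topography
exp(−d/λ), λ = 0.4, d the montage distance from the AF3–AF4 midpoint,
normalized to the frontal-pole amplitude; onsets are Poisson. Line noise
is a pure sinusoid. The generator does **not** emulate inter-channel
correlation of neural sources, non-Gaussian rhythms, saccades, muscle
artifacts, electrode drift, or any topographic structure of the regimes
themselves — passing tests show the pipeline recovers the temporal
band-power structure it models, not that it handles every property of
real recordings. The canned scenarios used by the tests are 60 s
recordings (four 15 s regimes at ≥10 dB in-band contrast; a
learning-shaped session with four diverse early regimes and one late
regime); these sizes keep the whole verification suite around a minute
of compute while leaving ≥25 STFT bins per regime.

**Cohort.** Per-treatment baseline score, linear per-session gain,
opposite-task mean, and workload shift, with Gaussian noise and clipping
to [0, 100]; hits/attempts are drawn so that score = 100·hits/attempts
holds exactly. The study-direction defaults encode the observed ordinal
pattern (virtual > real improvement; low > high abstraction trained
gain; high > low opposite-task score; workload falling under virtual
training and high abstraction) with baselines taken from the published
cognitive-task baselines. Group sizes default to the study's 6/6/6/7.

## Known limitations

* The entropy convention (pooled feature values per segment) is one of
  several defensible readings; published entropy tables cannot be
  reproduced numerically without the original recordings, so only the
  qualitative early > late direction is verified.
* Early/late split at the midpoint is a convention; results near the
  boundary depend on it.
* EDF output is 16-bit with per-channel physical ranges; round trips are
  exact only to the quantization step.
* ADJUST is reimplemented from its published feature definitions, not
  bit-compatible with the original toolbox; no EOG channels exist in
  this montage, so eye-movement detection is purely component-based.
* The automatic cut selection assumes one dominant scale gap in the
  dendrogram; slowly drifting (non-piecewise-stationary) activity can
  oversegment.
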