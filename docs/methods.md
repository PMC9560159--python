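# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Synthetic data generator

The generator produces spike data with exactly the statistical structure the
analyses assume, so recovery can be checked against ground truth.

**Stimuli.** Checkerboard noise is i.i.d. equiprobable ±1 per square per
frame; contrast is coded −1/+1 about the mean rather than 0/1, so the STA of
stimulus-independent spiking converges to 0 and null distributions of STA
pixels are centred. Defaults mirror a mesopic recording protocol: 66 ms
refresh, 150 µm squares, 200 × 10 s repeated clips, 30 min of nonrepeating
noise, 30 min of spontaneous activity (a photopic-style 33 ms / 75 µm
variant is a parameter change). The correlated "movie-like" stimulus is
spatially smoothed AR(1) Gaussian noise rescaled to unit variance, scaled by
1/3 and clipped to [−1, 1]; it reproduces a chosen lag-1 temporal
autocorrelation and spatial correlation length but makes no claim of
matching any particular natural movie's statistics.

**Ground-truth receptive fields.** Space: difference of Gaussians (centre
σ ∈ [0.9, 1.4] squares, surround 2.2–2.8 squares at weight 0.10–0.20 —
roughly 150–200 µm centre SDs on the mesopic grid, a realistic mouse RGC
scale). Time: difference of two gamma-like lobes
g(t; τ) = (t/τ)⁶ exp(−6(t/τ − 1)), w(t) = g(t; τ₁) − a·g(t; τ₂) with
τ₁ ∈ [60, 100] ms, τ₂ = 2τ₁ and a ∈ [0.45, 0.70], giving one sign change
and the closed-form zero crossing
t* = (6 ln(τ₂/τ₁) − ln a) / (6(1/τ₁ − 1/τ₂)) used by recovery tests. The
rendered volume is an exact outer product (second singular value 0 to
machine precision). The temporal filter is sampled at t = k·refresh for lag
k: with spikes uniformly jittered within their frame, the stimulus frame k
lags back sits on average k·refresh before the spike, so this sampling is
the one the STA estimates.

**Spiking.** Rates come from a cumulative-Gaussian contrast-response
function applied to the z-scored ground-truth generator signal; spikes are
per-frame Poisson counts with times uniform within the frame. This keeps
the simulator O(frames), aligns trial-to-trial variability with the Poisson
assumption of the CRF fitter, and makes per-frame count variance/mean ≈ 1
(a calibration the tests check). The template CRF is
r(g) = 1 + 30·Φ((g − 1)/0.6) Hz (~6–7 Hz mean drive, above the 3 Hz
inclusion rate used downstream); a degeneration stage scales the whole
curve by `gain_scale`, so the curve maximum scales exactly.

**Stages and cohorts.** A `StageConfig` sets gain scale, responsive
fraction, spontaneous baseline rate, and oscillation depth/frequency;
unresponsive cells are homogeneous Poisson at the baseline rate, mirroring
the unresponsive units that enter real recordings. Spontaneous activity is
Poisson with rate r₀(1 + d·sin 2πft) in 1 ms bins. Cells are grouped into
experiments (with alternating sex labels) so mixed-model analyses have a
grouping factor. All randomness descends from the stage seeds through
`numpy` SeedSequences; two cohorts built from the same configs are
bit-identical.

**What the generator does not emulate.** Real RGC spike trains are
typically sub-Poisson (refractoriness), adapt, and have correlated noise
across cells; receptive fields can be non-separable and nonlinearities
cell-type specific; natural movies are not AR(1) noise. Passing tests
therefore demonstrate correctness of the estimators under the LN-Poisson
model class, not robustness to every property of biological data. One
consequence is documented below (information stability).

## Receptive fields

*Lag convention:* lag 0 is the frame containing the spike; frames are
half-open intervals [t, t + Δ). Spikes without a full `n_lags` history are
dropped and counted. Default STA depth is 15 frames (~1 s at 66 ms); deep
enough to cover the slowest simulated filters with a quiet tail.

*SVD:* performed on the raw STA reshaped to (space × lag); no extra mean
subtraction (the ±1 coding already centres the stimulus), avoiding
distortion of low-SNR STAs. Separability score σ₁²/Σσᵢ² is computed on the
full STA (signal plus noise pixels), so added noise lowers it — the
intended behaviour for a quality criterion. The strict > 0.60 threshold is
configurable. Sign convention: the temporal filter's dominant lobe is made
positive, so the spatial centre sign encodes polarity (positive = ON; an
exactly zero centre is labelled ON).

*Gaussian fit:* elliptical 2-D Gaussian plus baseline, least squares,
initialised at the extremal pixel with σ = 1.5 squares. RF area is reported
at the 2-SD contour (π·2σ_major·2σ_minor); the contour choice is a
convention and is configurable.

*Temporal metrics:* the filter is biphasic when the global extremum and the
largest opposite-sign extremum at longer lag both exceed twice a noise
floor, estimated by default from the last 20 % of lags (far from the spike,
where the filter is ≈ 0). The zero crossing is linearly interpolated
between the bracketing samples, in ms from the spike (sample k at
k·refresh).

*SNR:* centre pixels are within Mahalanobis distance 2 of the fitted
Gaussian, far pixels beyond 4; values are read from the STA frame holding
the global absolute maximum, where signal is largest. A noiseless
compact-support STA has far-SD 0; the SNR is then capped at 10¹² and
flagged. Note that a broad surround leaks into the far pixels, so empirical
SNR is not purely noise-limited — a property of the metric, not a bug.

*Denoised filter:* for separable cells, `denoised_sta` replaces the STA by
its rank-1 reconstruction. The raw 30-min STA carries broadband estimation
noise across all space × lag dimensions; filtering the stimulus with it
caps the generator-signal correlation with the true drive near √(rank-1
fraction) ≈ 0.87, whereas the rank-1 reconstruction reaches ≥ 0.98. The
pipeline uses the denoised filter for separable cells and the raw STA
otherwise.

## LN model

The generator signal is z-scored over frames with a complete stimulus
history, making CRF parameters comparable across cells and stages. The CRF
is fit by Poisson maximum likelihood on per-frame counts (mean rate(g)·Δ),
from three fixed initialisations (best likelihood kept — deterministic
given the data), with L-BFGS-B bounds keeping rates nonnegative. Because a
constant-rate cell leaves the sigmoid unidentified (the optimiser can park
the midpoint outside the data with arbitrary r_max), the fitter also
evaluates a constant-rate model and keeps the sigmoid only when it earns
its three extra parameters under BIC; flat cells therefore return r_max = 0
with the observed mean rate as baseline. The cumulative Gaussian is the
default sigmoid, with the logistic available as an option — the two are
near-interchangeable in practice.

Prediction quality: the fraction of explainable variance is
corr(prediction, PSTH)² divided by the PSTH reliability (odd/even
trial-split correlation, Spearman–Brown corrected to the full trial count),
capped at 1. A shuffled prediction scores ≈ 0; a left-out trial-mean
prediction scores ≈ 1.

Responsiveness: variance/mean ratio of the summed-count PSTH at 33 ms bins
(two mesopic frames; configurable). Summed Poisson counts give ratio ≈ 1;
stimulus locking inflates it by the rate-modulation variance times the
trial count. The per-experiment threshold sits at the minimum-density
valley between the two most prominent modes of a Gaussian KDE on
log₁₀(ratio), falling back to a configured constant (default ratio 2) when
the distribution looks unimodal.

## Information

Direct method on binned repeat responses: words are sliding windows (stride
one bin), maximising sample count; per-bin counts are capped at 3 (at 4–6 ms
bins multi-spike bins are rare; configurable). H(R) is the entropy of the
pooled word distribution; H(R|S) averages the across-trial word entropy
over time epochs (uniform epoch weights, so the mixture identity
Σ P(s)P(r|s) = P(r) holds exactly). MI = H(R) − H(R|S), clipped to
[0, H(R)]; rate = MI / word duration; bits/spike divides by the mean rate
over the repeat block. Units below 3 Hz are excluded.

**Bin/word selection.** All (bin, word) pairs in 4–6 ms × 3–6 bins are
scanned; among pairs whose total entropy agrees with the Ma coincidence
bound within 5 % (relative), the smallest bin then longest word is adopted;
if none passes, the coarsest pair is returned flagged `undersampled`. The
Ma bound is computed per spike-count-per-word class k:
H_Ma = Σ p(k)(−log₂ P_c(k)) + H(p(k)), with P_c(k) the within-class pairwise
coincidence probability Σ n_w(n_w−1)/(N_k(N_k−1)); classes without a pair
are floored at 1/N² and flagged. No word-length extrapolation is performed.

**Estimators.** The default evaluates the entropy sums on empirical
probabilities ("plugin"): it satisfies exact identities (deterministic
responses give H(R|S) = 0 and MI = H(R); small tables match brute-force
summation to 10⁻¹²) but inherits the classic downward bias of plug-in
conditional entropies at finite trial counts — for a Poisson LN cell the
bias moves the rate by roughly 3 bits/s between 60 and 200 trials, and the
Ma-bound guard cannot catch it because the pooled marginal is well
sampled. For analyses that compare across trial counts, the
`estimator="grassberger"` option replaces both entropies by Grassberger
(1988) estimates and removes the residual 1/N bias of the noise entropy by
linear extrapolation in inverse trial count using the deterministic
even/odd trial split; under this estimator, subsampled rates at ≥ 60 of
200 trials agree with the full-data value within twice the resampling SD.
Real RGCs, being more reliable than Poisson, stabilise earlier; the
Poisson generator is the harder case.

Stability curves resample trials without replacement (and truncate clip
duration for the duration axis), reporting mean ± 2·SD across resamples;
the full-trial point reproduces the direct estimate with zero spread.

## Spontaneous activity

Counts at 1 ms, mean-subtracted, Welch spectra with 10 s segments and 50 %
overlap (0.1 Hz resolution, variance-reduced relative to one full-length
periodogram, which remains available), restricted to 0.1–35 Hz. Baseline
power is the mean over 0.1–2 Hz (flat for Poisson-like trains); the
fluctuation ratio divides the maximum power over 2–35 Hz by it. The search
band starts at 2 Hz so the baseline cannot feed its own numerator. The
oscillation threshold has no canonical value; the default 3 sits well above
the Poisson null (ratios ≈ 1.2, 95th percentile ≈ 2) and well below
strongly modulated cells (ratios > 10); tests also calibrate it directly as
the null's 95th percentile.

## Statistics and reports

KS comparisons use the exact two-sample D; p-values are exact where sample
sizes permit (scipy's "auto") because the purely asymptotic p is
anticonservative at cohort sizes (~8 % rejections at nominal 5 % with
n = 100 per group). Bonferroni multiplies by the family size — the number
of stage-vs-baseline comparisons per metric, configurable. Bootstrap
intervals are mean ± 2 SE with SE the SD of 2000 bootstrap means. The
mixed model is REML via statsmodels MixedLM: y ~ stage * sex with a
per-experiment random intercept; stage is categorical (one coefficient per
stage against the baseline), not a linear trend. Wald CIs on the stage
effect reach nominal coverage only with enough experiments per stage
(≈ 95 % at 8 per stage; markedly below nominal at 4) — a property of Wald
intervals with few groups, worth remembering when designing experiments.
Report tables star adjusted p-values at 0.1 / 0.01 / 0.001; note the first
level is 0.1, not the conventional 0.05.

`run_pipeline` chains generator → STA/SVD → Gaussian/temporal/SNR metrics
(separable cells) → CRF (all cells, denoised filter where separable) →
responsiveness → MI → PSD → per-stage summaries (means with bootstrap
±2 SE, nested 50/80/100 % percentile bands, separable / responsive /
oscillatory fractions) and KS comparisons against the baseline stage. Cells
are pooled across experiments within a stage for the KS comparisons;
per-cell tables retain the experiment label for per-experiment analyses. A
failing cell is logged and skipped, not fatal. Everything is deterministic
given the stage seeds.

## Problem sizes in tests

The test-suite and acceptance script use the protocol durations where the
property under test needs them (30 min checkerboards for RF/gain recovery;
30 min spontaneous traces for spectra; 200 × 10 s-scale repeat blocks for
information) on compact grids (8–12 squares per side), and smaller clips,
repeat counts and cohort sizes elsewhere (e.g. the end-to-end cohort runs
12 min of nonrepeating noise per cell, 30 × 5 s repeats, 2 min of
spontaneous activity); each choice is stated in the corresponding test or
script section. Where a measured quantity is intrinsically noisy at the
stated problem size (e.g. the binary-channel MI at 10⁴ words, sampling SD
≈ 1.3 %), tests average independent replicates of that size rather than
relying on a particular draw.

## Known limitations

- Estimator guarantees are established under the LN-Poisson generator; see
  "what the generator does not emulate" above.
- The Ma-bound variant (per-count-class pairwise coincidence) is one of
  several in the literature; it guards the marginal entropy only.
- The SNR numerator's "RF centre" pixel set (2-SD contour) and the RF-area
  contour are conventions; absolute values depend on them, comparisons
  across stages do not.
- ON brisk-sustained classification from autocorrelation functions is out
  of scope; only the ACF computation is provided.
- No direction-selectivity or non-separable RF models; such cells fail the
  separability criterion by design.
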