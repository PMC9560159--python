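# retsig

Analysis of retinal ganglion cell (RGC) signaling from multielectrode-array
spike trains, built for studies of photoreceptor degeneration: receptive-field
estimation, linear–nonlinear (LN) model fitting, direct-method mutual
information, oscillation detection in spontaneous activity, and cross-stage
statistics — together with a synthetic data generator that emulates
degeneration-stage cohorts, so every analysis stage is validated against
known ground truth.

## Who this is for

Retinal electrophysiologists and computational neuroscientists who record RGC
spikes in response to checkerboard noise and repeated stimulus clips and want
a tested, reproducible pipeline for the standard battery of analyses: How big
and fast are the receptive fields? How much does response gain change? How
many bits per second does each cell transmit? Is there pathological
oscillatory activity?

## The models and statistics at the core

**Receptive fields.** For spikes driven by binary checkerboard noise
(contrast coded ±1 about the mean), the spike-triggered average
STA(x, y, τ) estimates the linear spatiotemporal filter. SVD of the STA
reshaped to (space × lag) yields the best separable approximation
STA ≈ k(x, y) · w(τ); a cell is *space-time separable* when the rank-1 pair
captures > 60 % of the STA variance (σ₁² / Σᵢ σᵢ²). The spatial filter is
fit with an elliptical 2-D Gaussian (RF area at the 2-SD contour,
π·2σ_major·2σ_minor); the temporal filter, when biphasic, yields the
time-to-zero crossing between its two lobes; STA signal-to-noise is the
median of RF-centre pixels over the SD of pixels > 4 SD from the fitted
centre.

**LN model.** The generator signal g(t) = Σ STA·stimulus-history (z-scored)
feeds a static nonlinearity — the contrast-response function
r(g) = baseline + r_max·Φ((g − μ)/σ) — fitted by Poisson maximum likelihood
on per-frame spike counts. r_max is the gain read-out; prediction quality is
the fraction of explainable PSTH variance (trial-split reliability,
Spearman–Brown corrected). Light-responsiveness is classified from the
variance/mean ratio of the PSTH, thresholded at the valley of its bimodal
per-experiment distribution.

**Information.** For 200 repeats of a stimulus clip, spike trains are binned
(4–6 ms) and cut into sliding words of 3–6 bins. The direct method gives
I(S;R) = H(R) − H(R|S), where H(R) is the Shannon entropy of the pooled word
distribution and H(R|S) the mean across-trial word entropy per time epoch.
Bin size and word length are selected per cell by requiring the empirical
total entropy to agree with the Ma coincidence upper bound within 5 %, a
guard against undersampling; rates are reported in bits/s (MI divided by
word duration) and bits/spike. A Grassberger-corrected estimator with 1/N
extrapolation of the noise entropy is available for subsample-stability
analyses.

**Spontaneous activity.** Spike trains binned at 1 ms, Welch spectra over
0.1–35 Hz; the *fluctuation ratio* — maximum power in 2–35 Hz over mean
power in the flat 0.1–2 Hz baseline — flags oscillatory cells (flat Poisson
spectrum ⇒ ratio ≈ 1; sinusoidal rate modulation ⇒ a spectral line and a
large ratio).

**Statistics.** Stage-wise distributions are compared with two-sample
Kolmogorov–Smirnov tests, Bonferroni-corrected; means carry bootstrap
±2 SE intervals (2000 resamples); a linear mixed-effects model with a
per-experiment random intercept and a sex × stage interaction checks that
stage effects are not experiment- or sex-driven.

**Synthetic cohorts.** `make_cohort` simulates LN-Poisson RGCs
(difference-of-Gaussians × biphasic difference-of-gamma-lobes filters,
exactly rank 1, with closed-form time-to-zero) across degeneration stages
parameterised by gain scale, responsive fraction, and spontaneous
oscillation depth/frequency — mirroring the phenomenology of progressive
rod-then-cone degeneration, where gain falls steadily, the responsive
fraction shrinks, and ~5 Hz oscillations appear only after light responses
are lost.

## Worked example

```python
import retsig

# --- simulate one ON cell: 30 min of 66 ms / 150 um checkerboard ---
stim = retsig.make_checkerboard(12, 12, 27272, refresh_ms=66.0,
                                square_size_um=150.0, seed=0)
rf = retsig.GroundTruthRF(center_row=6, center_col=5, sigma_center=1.2,
                          sigma_surround=2.5, surround_weight=0.15,
                          tau1_ms=80.0, tau2_ms=160.0, lobe_ratio=0.6)
crf = retsig.default_crf_template()
spikes = retsig.simulate_ln_spike_train(stim, rf, crf, seed=1)

# --- receptive field ---
sta = retsig.compute_sta(spikes, stim, n_lags=15)
sep = retsig.svd_decompose(sta)
fit = retsig.fit_rf_gaussian(sep.spatial, stim.square_size_um)
tm = retsig.temporal_metrics(sep.temporal, stim.refresh_ms)

# --- information from 200 repeats of a 10 s clip ---
clip = retsig.make_checkerboard(12, 12, 151, 66.0, 150.0, seed=2)
trials = retsig.simulate_ln_trials(clip, rf, crf, n_trials=200, seed=3)
est = retsig.mutual_information(trials)

# --- oscillation detection on 30 min of spontaneous activity ---
spont = retsig.simulate_spontaneous(1800.0, baseline_rate_hz=8.0,
                                    osc_freq_hz=5.0, osc_depth=0.8, seed=4)
psd = retsig.compute_psd(spont)
flag, peak = retsig.detect_oscillation(psd, ratio_threshold=3.0)
```

This prints (via the obvious `print` statements):

```
rank-1 variance fraction: 0.762  (separable: True)
polarity: ON   RF area: 327.7 x 10^3 um^2
time-to-zero: 122.1 ms  (ground truth 124.5 ms)
STA SNR: 14.7
MI: 8.42 bits/s (1.27 bits/spike) at 4 ms bins x 6-bin words
fluctuation ratio: 9.6  oscillatory: True at 5.0 Hz
```

Reading: the rank-1 pair captures 76 % of the STA variance, well above the
60 % separability criterion; the recovered time-to-zero (122 ms) sits within
a fraction of a frame of the generator's analytic crossing (124.5 ms); the
cell transmits ~8 bits/s about the repeated clip at the selected 4 ms × 6-bin
words; and the 5 Hz, depth-0.8 modulated spontaneous train is flagged
oscillatory with its spectral peak at exactly 5 Hz.

For a full multi-stage cohort, build a `PipelineConfig` from a list of
`StageConfig`s and call `retsig.run_pipeline(cfg)`; the returned
`CohortReport` carries per-cell metrics, per-stage summaries with nested
50/80/100 % percentile bands and bootstrap intervals, and Bonferroni-adjusted
KS comparisons against the baseline stage (`report.to_csv(out_dir)` writes
the tables).

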