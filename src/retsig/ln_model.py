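"""Linear–nonlinear model fitting and evaluation.

The LN model describes a retinal ganglion cell as a linear spatiotemporal
filter (the STA) followed by a static nonlinearity (the contrast-response
function, CRF) and Poisson spike generation.  This module computes the
generator signal (stimulus filtered by the STA), fits the CRF by Poisson
maximum likelihood, predicts PSTHs, scores predictions by the fraction of
explainable variance, and classifies cells as light-responsive from the
variance/mean ratio of their PSTH.

The generator signal is z-scored, which makes CRF parameters (midpoint,
width in generator units) comparable across cells and recording sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import optimize, signal, stats

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .receptive_fields import STA
    from .synthetic import Stimulus, TrialSet

__all__ = [
    "ContrastResponseFunction",
    "GeneratorSignal",
    "PredictionQuality",
    "ResponsivenessResult",
    "generator_signal",
    "fit_crf",
    "crf_values_at",
    "predict_psth",
    "rate_to_psth_bins",
    "explainable_variance",
    "responsiveness",
    "responsiveness_threshold",
]


# --------------------------------------------------------------------------
# contrast-response function (static nonlinearity)
# --------------------------------------------------------------------------

@dataclass
class ContrastResponseFunction:
    """Parametric static nonlinearity mapping generator signal to rate (Hz).

    ``rate(g) = baseline + r_max * S((g - midpoint) / width)`` where ``S`` is
    the standard-normal CDF (default) or the logistic sigmoid.  Both are
    monotone, so the fitted rate is nondecreasing in the generator signal and
    bounded in ``[baseline, baseline + r_max]``.
    """

    r_max: float
    midpoint: float
    width: float
    baseline: float = 0.0
    family: str = "cumulative_gaussian"
    degenerate: bool = False

    def __post_init__(self):
        if self.r_max < 0 or self.baseline < 0:
            raise ValueError("r_max and baseline must be nonnegative rates")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.family not in ("cumulative_gaussian", "logistic"):
            raise ValueError(f"unknown CRF family {self.family!r}")

    def rate(self, g) -> np.ndarray:
        z = (np.asarray(g, dtype=float) - self.midpoint) / self.width
        if self.family == "cumulative_gaussian":
            s = stats.norm.cdf(z)
        else:
            s = 1.0 / (1.0 + np.exp(-z))
        return self.baseline + self.r_max * s

    __call__ = rate

    @property
    def max_rate(self) -> float:
        return self.baseline + self.r_max

    def scaled(self, gain: float) -> "ContrastResponseFunction":
        """Uniformly scale the whole curve (baseline and modulation) by ``gain``."""
        return ContrastResponseFunction(
            r_max=self.r_max * gain,
            midpoint=self.midpoint,
            width=self.width,
            baseline=self.baseline * gain,
            family=self.family,
        )


@dataclass
class GeneratorSignal:
    """Per-frame generator signal, z-scored over valid frames.

    The first ``n_invalid`` frames lack a full stimulus history and are NaN.
    """

    values: np.ndarray
    frame_times_s: np.ndarray
    n_invalid: int
    refresh_ms: float

    @property
    def valid(self) -> np.ndarray:
        return self.values[self.n_invalid:]


@dataclass
class PredictionQuality:
    fraction_explainable_variance: float
    predicted_psth: np.ndarray
    observed_psth: np.ndarray
    reliability: float
    capped: bool = False


@dataclass
class ResponsivenessResult:
    variance_mean_ratio: float
    threshold: float | None = None
    is_responsive: bool | None = None


# --------------------------------------------------------------------------
# generator signal
# --------------------------------------------------------------------------

def generator_signal(sta: "STA", stimulus: "Stimulus") -> GeneratorSignal:
    """Filter the stimulus with the STA to obtain one scalar per frame.

    ``g[t] = sum_{pixels, lags} STA[p, k] * stimulus[p, t - k]``; frames with
    an incomplete stimulus history (t < n_lags - 1) are marked invalid.  The
    valid samples are z-scored (mean 0, SD 1).
    """
    vol = np.asarray(sta.volume, dtype=float)
    frames = np.asarray(stimulus.frames, dtype=float)
    if vol.shape[:2] != frames.shape[:2]:
        raise ValueError(
            f"STA grid {vol.shape[:2]} does not match stimulus grid {frames.shape[:2]}"
        )
    n_lags = vol.shape[2]
    n_frames = frames.shape[2]
    if n_frames <= n_lags:
        raise ValueError("stimulus must be longer than the STA depth")

    flat_sta = vol.reshape(-1, n_lags)            # (pixels, lags)
    flat_stim = frames.reshape(-1, n_frames)      # (pixels, frames)
    raw = np.zeros(n_frames)
    for k in range(n_lags):
        # contribution of the frame k steps in the past
        raw[k:] += flat_sta[:, k] @ flat_stim[:, : n_frames - k]
    raw[: n_lags - 1] = np.nan

    valid = raw[n_lags - 1:]
    mu, sd = valid.mean(), valid.std()
    if sd == 0:
        raise ValueError("generator signal has zero variance; cannot z-score")
    values = (raw - mu) / sd
    dt = stimulus.refresh_ms / 1000.0
    times = (np.arange(n_frames) + 0.5) * dt
    return GeneratorSignal(values=values, frame_times_s=times,
                           n_invalid=n_lags - 1, refresh_ms=stimulus.refresh_ms)


# --------------------------------------------------------------------------
# CRF fitting (Poisson maximum likelihood)
# --------------------------------------------------------------------------

def _neg_log_likelihood(theta, g, counts, dt, family):
    r_max, mid, width, base = theta
    crf = ContrastResponseFunction(max(r_max, 0.0), mid, max(width, 1e-3),
                                   max(base, 0.0), family=family)
    mu = np.maximum(crf.rate(g) * dt, 1e-12)
    return float(np.sum(mu - counts * np.log(mu)))


def fit_crf(generator: GeneratorSignal, counts: np.ndarray, refresh_ms: float,
            family: str = "cumulative_gaussian") -> ContrastResponseFunction:
    """Fit the CRF by maximum likelihood under per-frame Poisson counts.

    ``counts`` holds the spike count of each stimulus frame (same length as
    the generator).  The per-frame Poisson mean is ``rate(g) * refresh``.
    The fit is deterministic: three fixed initialisations are run and the
    best likelihood kept.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != generator.values.shape:
        raise ValueError("counts must align with generator frames")
    if np.any(counts < 0):
        raise ValueError("spike counts must be nonnegative")
    g = generator.valid
    c = counts[generator.n_invalid:]
    if g.size < 100:
        raise ValueError("need at least 100 valid frames to fit a CRF")
    if not np.any(c > 0):
        return ContrastResponseFunction(0.0, 0.0, 1.0, 0.0, family=family,
                                        degenerate=True)

    dt = refresh_ms / 1000.0
    mean_rate = c.mean() / dt
    top_rate = np.quantile(c, 0.999) / dt
    inits = [
        (max(2 * mean_rate, 1.0), 1.0, 0.7, 0.25 * mean_rate),
        (max(top_rate, 1.0), 0.5, 0.5, 0.1 * mean_rate),
        (max(4 * mean_rate, 1.0), 2.0, 1.0, 0.5 * mean_rate),
    ]
    bounds = [(0.0, None), (-10.0, 10.0), (5e-2, 20.0), (0.0, None)]
    best = None
    for x0 in inits:
        res = optimize.minimize(
            _neg_log_likelihood, x0=np.asarray(x0), args=(g, c, dt, family),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res

    # a constant-rate cell leaves the sigmoid unidentified (the optimiser
    # parks the midpoint far outside the data); select flat vs sigmoid by BIC
    mu_flat = np.maximum(mean_rate * dt, 1e-12)
    nll_flat = float(np.sum(mu_flat - c * np.log(mu_flat)))
    if 2.0 * (nll_flat - best.fun) <= 3.0 * np.log(g.size):
        return ContrastResponseFunction(0.0, 0.0, 1.0, mean_rate,
                                        family=family)
    r_max, mid, width, base = best.x
    return ContrastResponseFunction(max(r_max, 0.0), mid, max(width, 5e-2),
                                    max(base, 0.0), family=family)


def crf_values_at(crf: ContrastResponseFunction, quantiles: Sequence[float],
                  generator_values: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the fitted curve at generator-signal quantiles.

    If pooled generator samples are given, the empirical quantiles are used;
    otherwise the z-scored generator is treated as standard normal and the
    quantiles taken from its CDF.
    """
    q = np.asarray(quantiles, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantiles must lie strictly within (0, 1)")
    if generator_values is not None:
        pts = np.quantile(np.asarray(generator_values, dtype=float), q)
    else:
        pts = stats.norm.ppf(q)
    return crf.rate(pts)


def predict_psth(sta: "STA", crf: ContrastResponseFunction,
                 stimulus: "Stimulus") -> np.ndarray:
    """LN-model firing-rate prediction per stimulus frame, in Hz.

    Frames without a full stimulus history are predicted at the rate for a
    zero generator signal.
    """
    gen = generator_signal(sta, stimulus)
    values = gen.values.copy()
    values[: gen.n_invalid] = 0.0
    return crf.rate(values)


def rate_to_psth_bins(rate_hz: np.ndarray, refresh_ms: float, bin_ms: float,
                      n_bins: int) -> np.ndarray:
    """Resample a per-frame rate onto PSTH bin centres (Hz)."""
    rate_hz = np.asarray(rate_hz, dtype=float)
    frame_centers = (np.arange(rate_hz.size) + 0.5) * refresh_ms / 1000.0
    bin_centers = (np.arange(n_bins) + 0.5) * bin_ms / 1000.0
    return np.interp(bin_centers, frame_centers, rate_hz)


# --------------------------------------------------------------------------
# prediction quality
# --------------------------------------------------------------------------

def _psth_hz(trials: "TrialSet", bin_ms: float) -> np.ndarray:
    """Trial-mean PSTH in Hz on a common bin grid (matrix helper below)."""
    return _trial_count_matrix(trials, bin_ms).mean(axis=0) / (bin_ms / 1000.0)


def _trial_count_matrix(trials: "TrialSet", bin_ms: float) -> np.ndarray:
    dt = bin_ms / 1000.0
    n_bins = int(np.floor(trials.clip_duration_s / dt + 1e-9))
    edges = np.arange(n_bins + 1) * dt
    rows = [np.histogram(t.times, bins=edges)[0] for t in trials.trials]
    return np.asarray(rows, dtype=float)


def explainable_variance(predicted_psth_hz: np.ndarray, trials: "TrialSet",
                         bin_ms: float) -> PredictionQuality:
    """Fraction of the explainable PSTH variance captured by a prediction.

    The explainable variance of the PSTH is estimated by trial-splitting:
    the correlation between odd- and even-trial mean PSTHs, Spearman-Brown
    corrected to the full trial count.  The reported fraction is
    ``corr(prediction, PSTH)^2 / reliability``, capped at 1.
    """
    if len(trials.trials) < 2:
        raise ValueError("need at least two trials to estimate reliability")
    m = _trial_count_matrix(trials, bin_ms)
    psth = m.mean(axis=0) / (bin_ms / 1000.0)
    pred = np.asarray(predicted_psth_hz, dtype=float)
    if pred.shape != psth.shape:
        raise ValueError(
            f"prediction has {pred.size} bins but the PSTH has {psth.size}"
        )

    odd = m[1::2].mean(axis=0)
    even = m[0::2].mean(axis=0)
    r_half = np.corrcoef(odd, even)[0, 1]
    reliability = 2 * r_half / (1 + r_half) if r_half > -1 else np.nan
    if not np.isfinite(reliability) or reliability <= 0:
        return PredictionQuality(np.nan, pred, psth, reliability, capped=False)

    r_pred = np.corrcoef(pred, psth)[0, 1]
    frac = r_pred ** 2 / reliability
    capped = frac > 1.0
    return PredictionQuality(min(frac, 1.0), pred, psth, reliability, capped)


# --------------------------------------------------------------------------
# light-responsiveness
# --------------------------------------------------------------------------

def responsiveness(trials: "TrialSet", bin_ms: float = 33.0,
                   threshold: float | None = None) -> ResponsivenessResult:
    """Variance/mean ratio of the summed-count PSTH.

    For a stimulus-independent Poisson unit the summed counts per bin are
    themselves Poisson, so the ratio sits near 1; stimulus-locked modulation
    inflates the variance across bins, pushing the ratio far above 1.
    """
    if len(trials.trials) < 2:
        raise ValueError("need at least two trials")
    counts = _trial_count_matrix(trials, bin_ms).sum(axis=0)
    mean = counts.mean()
    ratio = counts.var() / mean if mean > 0 else 0.0
    is_resp = None if threshold is None else bool(ratio > threshold)
    return ResponsivenessResult(ratio, threshold, is_resp)


def responsiveness_threshold(ratios: Sequence[float], fallback: float = 2.0,
                             grid_size: int = 512) -> float:
    """Per-experiment threshold separating the bimodal variance/mean ratios.

    A Gaussian kernel density is fit to log10(ratio); the threshold is placed
    at the minimum-density valley between the two most prominent modes.  If
    the distribution looks unimodal the configured fallback is returned.
    """
    x = np.log10(np.asarray(ratios, dtype=float))
    x = x[np.isfinite(x)]
    if x.size < 4 or np.ptp(x) < 1e-6:
        return fallback
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min() - 0.25, x.max() + 0.25, grid_size)
    dens = kde(grid)
    peaks, props = signal.find_peaks(dens, prominence=0.05 * dens.max())
    if peaks.size < 2:
        return fallback
    top_two = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top_two)
    valley = grid[lo + np.argmin(dens[lo:hi + 1])]
    return float(10 ** valley)
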