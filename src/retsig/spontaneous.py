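"""Power spectral analysis of spontaneous spiking and oscillation detection.

Degenerating retinas can develop rhythmic spontaneous RGC firing (~5 Hz).
To detect it, spontaneous spike trains are binned at 1 ms, mean-subtracted,
and a Welch-averaged power spectrum computed over 0.1-35 Hz.  The
"fluctuation ratio" is the maximum power over the 2-35 Hz search band
divided by the mean power over the flat 0.1-2 Hz baseline band; a Poisson
train has a flat spectrum (ratio near 1), while sinusoidal rate modulation
produces a spectral line at the modulation frequency and a large ratio.
The search band starts at 2 Hz so the baseline band cannot feed its own
numerator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, EmptyResultError

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SpikeTrain

__all__ = ["PSDResult", "compute_psd", "fluctuation_ratio", "detect_oscillation"]


@dataclass
class PSDResult:
    freqs: np.ndarray
    power: np.ndarray
    baseline_power: float
    peak_freq: float
    peak_power: float
    fluctuation_ratio: float
    band: tuple
    search_band: tuple


def compute_psd(spikes: "SpikeTrain", bin_ms: float = 1.0,
                band: tuple = (0.1, 35.0), baseline_band: tuple = (0.1, 2.0),
                search_band: tuple = (2.0, 35.0), segment_s: float = 10.0,
                method: str = "welch") -> PSDResult:
    """Spectrum of the binned, mean-subtracted spike train.

    Welch averaging with ``segment_s`` segments and 50% overlap (default
    10 s, giving 0.1 Hz resolution) reduces periodogram variance; a single
    full-length periodogram is available with ``method="periodogram"``.
    Requires at least 60 s of data so the 0.1 Hz baseline band is resolved.
    """
    if spikes.times.size == 0:
        raise EmptyResultError("empty spike train has no spectrum")
    if spikes.duration_s < 60.0:
        raise ValueError("need >= 60 s of data for 0.1 Hz resolution")
    fs = 1000.0 / bin_ms
    n_bins = int(np.floor(spikes.duration_s / (bin_ms / 1000.0)))
    counts = np.histogram(spikes.times,
                          bins=np.arange(n_bins + 1) * (bin_ms / 1000.0))[0]
    x = counts - counts.mean()
    if method == "welch":
        nper = int(round(segment_s * fs))
        freqs, power = signal.welch(x, fs=fs, nperseg=nper,
                                    noverlap=nper // 2)
    elif method == "periodogram":
        freqs, power = signal.periodogram(x, fs=fs)
    else:
        raise ValueError(f"unknown method {method!r}")

    mask = (freqs >= band[0]) & (freqs <= band[1])
    freqs, power = freqs[mask], power[mask]
    base_mask = (freqs >= baseline_band[0]) & (freqs <= baseline_band[1])
    baseline = float(power[base_mask].mean())
    s_mask = (freqs >= search_band[0]) & (freqs <= search_band[1])
    i_peak = int(np.argmax(power[s_mask]))
    peak_freq = float(freqs[s_mask][i_peak])
    peak_power = float(power[s_mask][i_peak])
    if baseline <= 0:
        raise DegenerateInputError("zero baseline power")
    return PSDResult(freqs=freqs, power=power, baseline_power=baseline,
                     peak_freq=peak_freq, peak_power=peak_power,
                     fluctuation_ratio=peak_power / baseline,
                     band=band, search_band=search_band)


def fluctuation_ratio(psd: PSDResult) -> float:
    """Maximum power over the search band divided by the baseline power."""
    if psd.baseline_power <= 0:
        raise DegenerateInputError("zero baseline power")
    s_mask = (psd.freqs >= psd.search_band[0]) & (psd.freqs <= psd.search_band[1])
    return float(psd.power[s_mask].max() / psd.baseline_power)


def detect_oscillation(psd: PSDResult, ratio_threshold: float = 3.0):
    """Flag a unit as oscillatory when its fluctuation ratio exceeds the
    threshold; returns ``(flag, peak_freq)``."""
    return bool(psd.fluctuation_ratio > ratio_threshold), psd.peak_freq
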