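"""Synthetic MEA-style data: stimuli, LN-Poisson RGCs, degeneration cohorts.

Photoreceptor degeneration alters retinal ganglion cell (RGC) output along
several axes: response gain shrinks, the fraction of light-responsive cells
drops, and (late in degeneration) spontaneous activity develops a ~5 Hz
oscillation.  This module generates spike data with exactly the statistical
structure the downstream analyses assume — linear–nonlinear Poisson cells
with space-time-separable receptive fields (difference-of-Gaussians space ×
biphasic time), cumulative-Gaussian contrast-response functions whose gain
scales with a "stage" parameter, and sinusoidally modulated Poisson
spontaneous activity — so every analysis stage can be validated against
known ground truth.

Conventions: checkerboard contrast is coded -1/+1 about the mean (so the
STA of stimulus-independent spiking converges to 0); spikes are emitted as
per-frame Poisson counts with times uniformly jittered within the frame,
matching the frame alignment of the STA.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .ln_model import ContrastResponseFunction

__all__ = [
    "Stimulus",
    "SpikeTrain",
    "TrialSet",
    "GroundTruthRF",
    "StageConfig",
    "CellRecord",
    "CohortDataset",
    "make_checkerboard",
    "make_correlated_movie",
    "simulate_ln_trials",
    "simulate_ln_spike_train",
    "simulate_spontaneous",
    "make_cohort",
    "true_generator_signal",
    "default_crf_template",
    "load_stage_configs",
    "write_spikes_csv",
    "read_spikes_csv",
    "save_cohort_hdf5",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Stimulus:
    """A space x space x time contrast volume.

    ``frames[r, c, t]`` holds the contrast of square (r, c) during frame t,
    coded about the mean level: exactly -1/+1 for checkerboard noise, within
    [-1, 1] for correlated movies.
    """

    frames: np.ndarray
    refresh_ms: float
    square_size_um: float
    mean_level: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def clip_duration_s(self) -> float:
        return self.n_frames * self.refresh_ms / 1000.0


@dataclass
class SpikeTrain:
    """Sorted spike times (seconds) for one unit over one recording."""

    unit_id: str
    times: np.ndarray
    duration_s: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (
            np.any(np.diff(self.times) < 0)
            or self.times[0] < 0
            or self.times[-1] >= self.duration_s
        ):
            raise ValueError("spike times must be sorted within [0, duration_s)")

    @property
    def rate_hz(self) -> float:
        return self.times.size / self.duration_s


@dataclass
class TrialSet:
    """Spike trains aligned to repeats of one stimulus clip."""

    trials: list
    clip_duration_s: float
    stimulus_ref: str | None = None

    def __post_init__(self):
        for t in self.trials:
            if abs(t.duration_s - self.clip_duration_s) > 1e-9:
                raise ValueError("all trials must share the clip duration")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def mean_rate_hz(self) -> float:
        n = sum(t.times.size for t in self.trials)
        return n / (self.n_trials * self.clip_duration_s)


@dataclass
class GroundTruthRF:
    """Separable ground-truth receptive field: DoG space x biphasic time.

    The temporal filter is a difference of two gamma-like lobes
    ``g(t; tau) = (t/tau)^n exp(-n (t/tau - 1))`` (unit peak at ``t = tau``):
    ``w(t) = g(t; tau1) - lobe_ratio * g(t; tau2)`` with ``tau2 > tau1``, so
    the zero crossing between the lobes has a closed form.  OFF polarity
    negates the rendered filter.
    """

    center_row: float
    center_col: float
    sigma_center: float            # grid units (squares)
    sigma_surround: float
    surround_weight: float
    tau1_ms: float
    tau2_ms: float
    lobe_ratio: float              # second-lobe amplitude relative to first
    polarity: str = "ON"
    n_exp: int = 6

    def __post_init__(self):
        if self.tau2_ms <= self.tau1_ms:
            raise ValueError("tau2_ms must exceed tau1_ms")
        if not (0 < self.lobe_ratio):
            raise ValueError("lobe_ratio must be positive")
        if self.polarity not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")

    @property
    def zero_crossing_ms(self) -> float:
        """Analytic zero crossing of the continuous temporal filter (ms)."""
        n = self.n_exp
        num = n * np.log(self.tau2_ms / self.tau1_ms) - np.log(self.lobe_ratio)
        den = n * (1.0 / self.tau1_ms - 1.0 / self.tau2_ms)
        return float(num / den)

    def spatial_filter(self, rows: int, cols: int) -> np.ndarray:
        r = np.arange(rows)[:, None]
        c = np.arange(cols)[None, :]
        d2 = (r - self.center_row) ** 2 + (c - self.center_col) ** 2
        center = np.exp(-d2 / (2 * self.sigma_center ** 2))
        surround = np.exp(-d2 / (2 * self.sigma_surround ** 2))
        return center - self.surround_weight * surround

    def temporal_filter(self, n_lags: int, refresh_ms: float) -> np.ndarray:
        """Filter sampled at ``t = k * refresh_ms``, lag 0 = the spike frame.

        With spikes uniformly jittered within their frame, the stimulus
        frame k lags back sits on average ``k * refresh`` before the spike,
        so this sampling matches the STA's lag convention.
        """
        t = np.arange(n_lags) * refresh_ms

        def lobe(tau):
            x = t / tau
            return x ** self.n_exp * np.exp(-self.n_exp * (x - 1.0))

        w = lobe(self.tau1_ms) - self.lobe_ratio * lobe(self.tau2_ms)
        return w

    def render(self, rows: int, cols: int, n_lags: int,
               refresh_ms: float) -> np.ndarray:
        """Unit-Frobenius-norm rank-1 spatiotemporal filter volume."""
        s = self.spatial_filter(rows, cols)
        w = self.temporal_filter(n_lags, refresh_ms)
        vol = s[:, :, None] * w[None, None, :]
        if self.polarity == "OFF":
            vol = -vol
        return vol / np.linalg.norm(vol)


@dataclass
class StageConfig:
    """Parameters of one degeneration stage of the simulated cohort."""

    stage_label: str
    gain_scale: float = 1.0
    responsive_fraction: float = 1.0
    osc_depth: float = 0.0
    osc_freq_hz: float = 5.0
    baseline_rate_hz: float = 5.0
    n_cells: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.gain_scale <= 1):
            raise ValueError("gain_scale must lie in (0, 1]")
        for name in ("responsive_fraction", "osc_depth"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class CellRecord:
    """One simulated cell with its generator parameters and responses."""

    unit_id: str
    stage_label: str
    experiment_id: str
    sex: str
    responsive: bool
    rf: GroundTruthRF
    crf: ContrastResponseFunction
    trials: TrialSet | None = None
    nonrepeat_spikes: SpikeTrain | None = None
    spontaneous: SpikeTrain | None = None


@dataclass
class CohortDataset:
    """Simulated multi-stage, multi-experiment cohort."""

    cells: list
    stages: list
    repeat_stimulus: Stimulus | None = None
    nonrepeat_stimulus: Stimulus | None = None


# --------------------------------------------------------------------------
# stimuli
# --------------------------------------------------------------------------

def make_checkerboard(rows: int, cols: int, n_frames: int, refresh_ms: float,
                      square_size_um: float = 150.0, seed: int = 0) -> Stimulus:
    """Binary checkerboard noise: i.i.d. equiprobable +-1 per square per frame."""
    if rows < 1 or cols < 1 or n_frames < 1:
        raise ValueError("rows, cols and n_frames must be positive")
    if refresh_ms <= 0:
        raise ValueError("refresh_ms must be positive")
    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 2, size=(rows, cols, n_frames)).astype(np.float32)
    frames = frames * 2.0 - 1.0
    return Stimulus(frames=frames, refresh_ms=refresh_ms,
                    square_size_um=square_size_um)


def make_correlated_movie(rows: int, cols: int, n_frames: int,
                          spatial_corr_len: float, temporal_ar1: float,
                          refresh_ms: float = 33.0,
                          square_size_um: float = 75.0,
                          seed: int = 0) -> Stimulus:
    """Correlated "natural-movie-like" noise clip.

    Gaussian noise given AR(1) temporal correlation (lag-1 autocorrelation
    ``temporal_ar1``) and Gaussian spatial smoothing with SD
    ``spatial_corr_len`` squares, rescaled to unit variance, then scaled by
    1/3 and clipped to [-1, 1] (clipping affects ~0.3% of samples).
    """
    if not (0 <= temporal_ar1 < 1):
        raise ValueError("temporal_ar1 must lie in [0, 1) for stationarity")
    if spatial_corr_len < 0:
        raise ValueError("spatial_corr_len must be nonnegative")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((rows, cols, n_frames))
    # stationary unit-variance AR(1) along time
    x = lfilter([np.sqrt(1.0 - temporal_ar1 ** 2)], [1.0, -temporal_ar1],
                eps, axis=2)
    if spatial_corr_len > 0:
        x = gaussian_filter(x, sigma=(spatial_corr_len, spatial_corr_len, 0))
        x /= x.std()
    frames = np.clip(x / 3.0, -1.0, 1.0).astype(np.float32)
    return Stimulus(frames=frames, refresh_ms=refresh_ms,
                    square_size_um=square_size_um)


# --------------------------------------------------------------------------
# LN-Poisson spike simulation
# --------------------------------------------------------------------------

def true_generator_signal(stimulus: Stimulus, rf: GroundTruthRF,
                          n_lags: int = 15) -> np.ndarray:
    """Ground-truth generator signal: stimulus filtered by the rendered RF.

    z-scored over frames with a full stimulus history; the first
    ``n_lags - 1`` frames (incomplete history) are set to 0, i.e. the mean
    drive.  This is exactly the drive the LN simulator converts to rates,
    so it serves as the oracle for generator-signal and CRF recovery.
    """
    rows, cols, n_frames = stimulus.frames.shape
    kernel = rf.render(rows, cols, n_lags, stimulus.refresh_ms)
    flat_k = kernel.reshape(-1, n_lags)
    flat_s = np.asarray(stimulus.frames, dtype=float).reshape(-1, n_frames)
    g = np.zeros(n_frames)
    for k in range(n_lags):
        g[k:] += flat_k[:, k] @ flat_s[:, : n_frames - k]
    valid = g[n_lags - 1:]
    sd = valid.std()
    if sd > 0:
        g = (g - valid.mean()) / sd
    g[: n_lags - 1] = 0.0
    return g


def _ln_rate_per_frame(stimulus: Stimulus, rf: GroundTruthRF,
                       crf: ContrastResponseFunction, n_lags: int) -> np.ndarray:
    rate = crf.rate(true_generator_signal(stimulus, rf, n_lags))
    if np.any(~np.isfinite(rate)) or np.any(rate < 0):
        raise ValueError("CRF produced non-finite or negative rates")
    return rate


def _poisson_frame_spikes(rate_hz: np.ndarray, refresh_ms: float,
                          rng: np.random.Generator) -> np.ndarray:
    dt = refresh_ms / 1000.0
    counts = rng.poisson(rate_hz * dt)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(np.arange(rate_hz.size) * dt, counts)
    times = starts + rng.uniform(0.0, dt, size=total)
    return np.sort(times)


def simulate_ln_trials(stimulus: Stimulus, rf: GroundTruthRF,
                       crf: ContrastResponseFunction, n_trials: int,
                       seed: int = 0, n_lags: int = 15,
                       unit_id: str = "sim") -> TrialSet:
    """Simulate repeated LN-Poisson responses to one stimulus clip.

    Per frame the spike count is Poisson with mean ``rate * refresh`` where
    ``rate = crf(generator signal)``; spike times are uniform within the
    frame.  Trials are independent given the shared stimulus.
    """
    rate = _ln_rate_per_frame(stimulus, rf, crf, n_lags)
    rng = np.random.default_rng(seed)
    dur = stimulus.clip_duration_s
    trials = [
        SpikeTrain(f"{unit_id}/trial{i}",
                   np.clip(_poisson_frame_spikes(rate, stimulus.refresh_ms, rng),
                           0.0, np.nextafter(dur, 0.0)),
                   dur)
        for i in range(n_trials)
    ]
    return TrialSet(trials=trials, clip_duration_s=dur, stimulus_ref=unit_id)


def simulate_ln_spike_train(stimulus: Stimulus, rf: GroundTruthRF,
                            crf: ContrastResponseFunction, seed: int = 0,
                            n_lags: int = 15,
                            unit_id: str = "sim") -> SpikeTrain:
    """Single long LN-Poisson response (e.g. to nonrepeating checkerboard)."""
    ts = simulate_ln_trials(stimulus, rf, crf, 1, seed=seed, n_lags=n_lags,
                            unit_id=unit_id)
    tr = ts.trials[0]
    return SpikeTrain(unit_id, tr.times, tr.duration_s)


def simulate_spontaneous(duration_s: float, baseline_rate_hz: float,
                         osc_freq_hz: float = 5.0, osc_depth: float = 0.0,
                         seed: int = 0, unit_id: str = "spont") -> SpikeTrain:
    """Poisson spontaneous activity with optional sinusoidal rate modulation.

    ``r(t) = r0 * (1 + osc_depth * sin(2 pi f t))``; depth <= 1 keeps the
    rate nonnegative.  Simulated as Poisson counts in 1 ms bins with uniform
    jitter within the bin.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not (0 <= osc_depth <= 1):
        raise ValueError("osc_depth must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dt = 1e-3
    n = int(round(duration_s / dt))
    t = (np.arange(n) + 0.5) * dt
    rate = baseline_rate_hz * (1.0 + osc_depth * np.sin(2 * np.pi * osc_freq_hz * t))
    counts = rng.poisson(rate * dt)
    total = int(counts.sum())
    starts = np.repeat(np.arange(n) * dt, counts)
    times = np.sort(starts + rng.uniform(0, dt, size=total))
    times = np.clip(times, 0.0, np.nextafter(duration_s, 0.0))
    return SpikeTrain(unit_id, times, duration_s)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

#: CRF template shared by all responsive cells before gain scaling.  r_max
#: 30 Hz with a midpoint one generator-SD above the mean gives ~6 Hz mean
#: drive, comfortably above the 3 Hz inclusion rate used downstream.
def default_crf_template() -> ContrastResponseFunction:
    return ContrastResponseFunction(r_max=30.0, midpoint=1.0, width=0.6,
                                    baseline=1.0)


def _random_rf(rng: np.random.Generator, rows: int, cols: int) -> GroundTruthRF:
    margin_r, margin_c = 0.3 * rows, 0.3 * cols
    tau1 = rng.uniform(60.0, 100.0)
    return GroundTruthRF(
        center_row=rng.uniform(margin_r, rows - margin_r),
        center_col=rng.uniform(margin_c, cols - margin_c),
        sigma_center=rng.uniform(0.9, 1.4),
        sigma_surround=rng.uniform(2.2, 2.8),
        surround_weight=rng.uniform(0.10, 0.20),
        tau1_ms=tau1,
        tau2_ms=2.0 * tau1,
        lobe_ratio=rng.uniform(0.45, 0.70),
        polarity="ON" if rng.random() < 0.5 else "OFF",
    )


def make_cohort(stage_configs: Sequence[StageConfig],
                cells_per_experiment: int | None = None,
                n_experiments: int = 2, *,
                rows: int = 12, cols: int = 12,
                refresh_ms: float = 66.0, square_size_um: float = 150.0,
                n_lags: int = 15,
                n_repeats: int = 200, clip_s: float = 10.0,
                nonrepeat_s: float = 1800.0, spont_s: float = 1800.0,
                crf_template: ContrastResponseFunction | None = None,
                simulate_repeats: bool = True,
                simulate_nonrepeating: bool = True,
                simulate_spont: bool = True) -> CohortDataset:
    """Simulate a multi-stage, multi-experiment cohort of LN-RGCs.

    Per stage, a fraction ``responsive_fraction`` of cells are LN cells with
    the template CRF uniformly scaled by ``gain_scale``; the rest are
    homogeneous Poisson at ``baseline_rate_hz`` (unresponsive units enter
    real recordings too).  All generator parameters are stored on each
    ``CellRecord`` so recovery error is computable.  Deterministic given the
    stage seeds.  Defaults mirror the recording protocol the analyses
    assume: 66 ms / 150 um mesopic checkerboard, 200 x 10 s repeats, 30 min
    nonrepeating noise, 30 min spontaneous activity.
    """
    if len(stage_configs) == 0:
        raise ValueError("need at least one stage")
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    template = crf_template or default_crf_template()

    base_seed = stage_configs[0].seed
    stim_ss = np.random.SeedSequence([base_seed, 0xC0FFEE])
    s1, s2 = stim_ss.spawn(2)
    repeat_stim = nonrepeat_stim = None
    if simulate_repeats:
        repeat_stim = make_checkerboard(
            rows, cols, int(round(clip_s * 1000 / refresh_ms)), refresh_ms,
            square_size_um, seed=s1)
    if simulate_nonrepeating:
        nonrepeat_stim = make_checkerboard(
            rows, cols, int(round(nonrepeat_s * 1000 / refresh_ms)), refresh_ms,
            square_size_um, seed=s2)

    cells = []
    for stage in stage_configs:
        n_cells = cells_per_experiment or stage.n_cells
        ss = np.random.SeedSequence([stage.seed, 0x5EED])
        for e in range(n_experiments):
            exp_id = f"{stage.stage_label}_exp{e}"
            sex = "M" if e % 2 == 0 else "F"
            for c in range(n_cells):
                child = ss.spawn(1)[0]
                rng = np.random.default_rng(child)
                rf = _random_rf(rng, rows, cols)
                responsive = bool(rng.random() < stage.responsive_fraction)
                if responsive:
                    crf = template.scaled(stage.gain_scale)
                else:
                    crf = ContrastResponseFunction(
                        r_max=0.0, midpoint=0.0, width=1.0,
                        baseline=stage.baseline_rate_hz)
                uid = f"{exp_id}/cell{c}"
                seeds = rng.integers(0, 2 ** 31, size=3)
                rec = CellRecord(uid, stage.stage_label, exp_id, sex,
                                 responsive, rf, crf)
                if simulate_repeats:
                    rec.trials = simulate_ln_trials(
                        repeat_stim, rf, crf, n_repeats, seed=int(seeds[0]),
                        n_lags=n_lags, unit_id=uid)
                if simulate_nonrepeating:
                    rec.nonrepeat_spikes = simulate_ln_spike_train(
                        nonrepeat_stim, rf, crf, seed=int(seeds[1]),
                        n_lags=n_lags, unit_id=uid)
                if simulate_spont:
                    rec.spontaneous = simulate_spontaneous(
                        spont_s, stage.baseline_rate_hz, stage.osc_freq_hz,
                        stage.osc_depth, seed=int(seeds[2]), unit_id=uid)
                cells.append(rec)
    return CohortDataset(cells=cells, stages=list(stage_configs),
                         repeat_stimulus=repeat_stim,
                         nonrepeat_stimulus=nonrepeat_stim)


# --------------------------------------------------------------------------
# I/O: tabular text and hierarchical binary container
# --------------------------------------------------------------------------

def load_stage_configs(path) -> list:
    """Read StageConfigs from a YAML file.

    Schema: a top-level ``stages`` list whose entries carry the StageConfig
    fields (``stage_label`` required; ``gain_scale``, ``responsive_fraction``,
    ``osc_depth``, ``osc_freq_hz``, ``baseline_rate_hz``, ``n_cells``,
    ``seed`` optional with the dataclass defaults)::

        stages:
          - {stage_label: WT, gain_scale: 1.0, seed: 1}
          - {stage_label: 5mo, gain_scale: 0.5, responsive_fraction: 0.7, seed: 2}
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "stages" not in doc:
        raise ValueError("config must contain a top-level 'stages' list")
    return [StageConfig(**entry) for entry in doc["stages"]]


def write_spikes_csv(path, trial_sets: dict):
    """Write ``{unit_id: TrialSet}`` as CSV rows (unit_id, trial, spike_time_s)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", "trial", "spike_time_s"])
        for uid, ts in trial_sets.items():
            for i, tr in enumerate(ts.trials):
                for t in tr.times:
                    w.writerow([uid, i, f"{t:.6f}"])


def read_spikes_csv(path, clip_duration_s: float) -> dict:
    """Read the CSV written by :func:`write_spikes_csv` back into TrialSets."""
    raw: dict = {}
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        for row in r:
            raw.setdefault(row["unit_id"], {}).setdefault(
                int(row["trial"]), []).append(float(row["spike_time_s"]))
    out = {}
    for uid, trials in raw.items():
        tr = [
            SpikeTrain(f"{uid}/trial{i}", np.sort(trials[i]), clip_duration_s)
            for i in sorted(trials)
        ]
        out[uid] = TrialSet(tr, clip_duration_s)
    return out


def save_cohort_hdf5(path, cohort: CohortDataset):
    """Store cohort spike data hierarchically: one group per unit, one
    dataset per trial, plus spontaneous/nonrepeating trains as datasets."""
    import h5py

    with h5py.File(path, "w") as f:
        for cell in cohort.cells:
            g = f.create_group(cell.unit_id)
            g.attrs["stage"] = cell.stage_label
            g.attrs["experiment"] = cell.experiment_id
            g.attrs["sex"] = cell.sex
            g.attrs["responsive"] = cell.responsive
            if cell.trials is not None:
                tg = g.create_group("trials")
                tg.attrs["clip_duration_s"] = cell.trials.clip_duration_s
                for i, tr in enumerate(cell.trials.trials):
                    tg.create_dataset(f"trial{i}", data=tr.times)
            if cell.nonrepeat_spikes is not None:
                d = g.create_dataset("nonrepeating",
                                     data=cell.nonrepeat_spikes.times)
                d.attrs["duration_s"] = cell.nonrepeat_spikes.duration_s
            if cell.spontaneous is not None:
                d = g.create_dataset("spontaneous", data=cell.spontaneous.times)
                d.attrs["duration_s"] = cell.spontaneous.duration_s
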