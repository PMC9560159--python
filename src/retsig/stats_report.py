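"""Cross-stage statistics and cohort-level report generation.

Distributions of per-cell metrics (RF area, time-to-zero, STA SNR, CRF
values, information rates, fluctuation ratios) are compared across
degeneration stages with the two-sample Kolmogorov-Smirnov test, Bonferroni
corrected over the family of stage-vs-baseline comparisons; means carry
bootstrap +-2 SE intervals (2000 resamples); and a linear mixed-effects
model with experiment as a random intercept and a sex x stage interaction
checks that stage effects are not driven by experiment-to-experiment
variability.  ``run_pipeline`` orchestrates the full chain
simulate -> RF -> LN -> information -> PSD -> statistics on a synthetic
cohort and emits tabular summaries.

Star convention used in report tables: *, **, *** for adjusted p < 0.1,
0.01, 0.001 (note the unconventional 0.1 level of the first star).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import information, ln_model, receptive_fields, spontaneous
from .errors import RetsigError
from .synthetic import StageConfig, make_cohort

__all__ = [
    "ComparisonResult",
    "BootstrapSummary",
    "LmmResult",
    "PipelineConfig",
    "CohortReport",
    "ks_two_sample",
    "bonferroni",
    "bootstrap_mean",
    "fit_random_intercept_lmm",
    "run_pipeline",
    "significance_stars",
]


@dataclass
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    d_statistic: float
    p_raw: float
    p_adjusted: float | None = None
    family_size: int | None = None


@dataclass
class BootstrapSummary:
    mean: float
    lower: float
    upper: float
    se: float
    n_boot: int
    seed: int


@dataclass
class LmmResult:
    fixed_effects: dict
    fixed_se: dict
    random_intercept_var: float
    residual_var: float
    log_likelihood: float
    converged: bool
    dropped_columns: list = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Everything needed for a deterministic end-to-end cohort run.

    Defaults mirror the recording protocol (30 min nonrepeating
    checkerboard, 200 x 10 s repeats, 30 min spontaneous); tests and quick
    runs pass smaller durations.
    """

    stages: Sequence[StageConfig]
    cells_per_experiment: int = 5
    n_experiments: int = 2
    rows: int = 12
    cols: int = 12
    refresh_ms: float = 66.0
    square_size_um: float = 150.0
    n_lags: int = 15
    n_repeats: int = 200
    clip_s: float = 10.0
    nonrepeat_s: float = 1800.0
    spont_s: float = 1800.0
    separability_threshold: float = 0.60
    responsiveness_bin_ms: float = 33.0
    crf_quantiles: tuple = (0.25, 0.5, 0.75, 0.9)
    info_bin_range: tuple = (4.0, 5.0, 6.0)
    info_word_range: tuple = (3, 4, 5, 6)
    info_tolerance: float = 0.05
    min_rate_hz: float = 3.0
    osc_ratio_threshold: float = 3.0
    baseline_stage: str | None = None   # default: first stage
    compute_info: bool = True
    compute_psd: bool = True


@dataclass
class CohortReport:
    per_cell: pd.DataFrame
    per_stage: pd.DataFrame
    comparisons: list
    errors: list
    config: PipelineConfig

    def to_csv(self, out_dir):
        import pathlib

        d = pathlib.Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        self.per_cell.to_csv(d / "per_cell_metrics.csv", index=False)
        self.per_stage.to_csv(d / "per_stage_summary.csv", index=False)
        pd.DataFrame([c.__dict__ for c in self.comparisons]).to_csv(
            d / "stage_comparisons.csv", index=False)


# --------------------------------------------------------------------------
# elementary statistics
# --------------------------------------------------------------------------

def ks_two_sample(x, y, metric: str = "", labels=("a", "b")) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum of the ECDF difference; the p-value is exact
    where sample sizes permit and asymptotic otherwise (the purely
    asymptotic p is anticonservative at cohort-sized samples).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, method="auto")
    return ComparisonResult(metric, labels[0], labels[1],
                            float(res.statistic), float(res.pvalue))


def bonferroni(pvals, family_size: int | None = None):
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    return np.minimum(1.0, p * m)


def significance_stars(p_adjusted: float) -> str:
    if p_adjusted < 0.001:
        return "***"
    if p_adjusted < 0.01:
        return "**"
    if p_adjusted < 0.1:
        return "*"
    return ""


def bootstrap_mean(x, n_boot: int = 2000, seed: int = 0) -> BootstrapSummary:
    """Bootstrap the sample mean; interval is mean +- 2 SE (SE = SD of the
    bootstrap means)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    rng = np.random.default_rng(seed)
    boots = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    se = float(boots.std(ddof=1))
    m = float(x.mean())
    return BootstrapSummary(m, m - 2 * se, m + 2 * se, se, n_boot, seed)


def fit_random_intercept_lmm(values, stage, sex, experiment_id,
                             stage_order: Sequence[str] | None = None) -> LmmResult:
    """REML fit of ``y ~ stage * sex`` with a per-experiment random intercept.

    Stage enters as an ordered categorical fixed effect (one coefficient per
    stage vs the first), sex and the sex x stage interaction as fixed
    effects; experiment-to-experiment variability is absorbed by the random
    intercept.  Degenerate columns (e.g. a single sex level) are dropped and
    listed.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(values, float),
        "stage": pd.Categorical(stage, categories=stage_order, ordered=stage_order is not None),
        "sex": pd.Categorical(sex),
        "experiment": list(experiment_id),
    })
    if df["experiment"].nunique() < 2:
        raise ValueError("need at least two experiments for a random intercept")
    dropped = []
    rhs = "C(stage) * C(sex)"
    if df["sex"].nunique() < 2:
        rhs = "C(stage)"
        dropped.append("sex and sex:stage (single sex level)")
    if df["stage"].nunique() < 2:
        raise ValueError("need at least two stages")
    model = smf.mixedlm(f"y ~ {rhs}", df, groups=df["experiment"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    return LmmResult(
        fixed_effects=dict(fit.fe_params),
        fixed_se=dict(fit.bse_fe),
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        log_likelihood=float(fit.llf),
        converged=bool(fit.converged),
        dropped_columns=dropped,
    )


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------

_BAND_PCTS = {"p0": 0, "p10": 10, "p25": 25, "p50": 50, "p75": 75,
              "p90": 90, "p100": 100}

_COMPARED_METRICS = ("rf_area_um2", "time_to_zero_ms", "snr",
                     "crf_q90_hz", "mi_bits_per_s", "fluctuation_ratio")


def _analyze_cell(cell, cohort, cfg: PipelineConfig) -> dict:
    row = {
        "unit_id": cell.unit_id, "stage": cell.stage_label,
        "experiment": cell.experiment_id, "sex": cell.sex,
        "true_responsive": cell.responsive,
        "true_gain": cell.crf.max_rate,
    }
    sta = receptive_fields.compute_sta(cell.nonrepeat_spikes,
                                       cohort.nonrepeat_stimulus, cfg.n_lags)
    sep = receptive_fields.svd_decompose(sta)
    row["rank1_fraction"] = sep.rank1_variance_fraction
    row["polarity"] = sep.polarity
    separable = receptive_fields.classify_separable(sep,
                                                    cfg.separability_threshold)
    row["is_separable"] = separable
    if separable:
        fit = receptive_fields.fit_rf_gaussian(sep.spatial, cfg.square_size_um)
        row["rf_area_um2"] = fit.rf_area_um2
        tm = receptive_fields.temporal_metrics(sep.temporal, cfg.refresh_ms)
        row["time_to_zero_ms"] = tm.time_to_zero_ms
        try:
            row["snr"] = receptive_fields.sta_snr(sta, fit).snr
        except RetsigError:
            row["snr"] = np.nan

    # CRF does not require separability (unresponsive cells yield a flat
    # fit); separable cells use the rank-1 denoised STA as the filter.
    gen_sta = receptive_fields.denoised_sta(sta, sep) if separable else sta
    gen = ln_model.generator_signal(gen_sta, cohort.nonrepeat_stimulus)
    counts = information.bin_trials(
        _as_trialset(cell.nonrepeat_spikes), cfg.refresh_ms)[0]
    crf = ln_model.fit_crf(gen, counts, cfg.refresh_ms)
    vals = ln_model.crf_values_at(crf, cfg.crf_quantiles,
                                  generator_values=gen.valid)
    for q, v in zip(cfg.crf_quantiles, vals):
        row[f"crf_q{int(q * 100)}_hz"] = v
    row["fitted_r_max"] = crf.r_max

    resp = ln_model.responsiveness(cell.trials, cfg.responsiveness_bin_ms)
    row["variance_mean_ratio"] = resp.variance_mean_ratio

    if cfg.compute_info:
        try:
            est = information.mutual_information(
                cell.trials, cfg.info_bin_range, cfg.info_word_range,
                cfg.info_tolerance, min_rate_hz=cfg.min_rate_hz)
            row["mi_bits_per_s"] = est.rate_bits_per_s
            row["bits_per_spike"] = est.bits_per_spike
            row["mi_undersampled"] = est.undersampled
        except ValueError:
            row["mi_bits_per_s"] = np.nan
    if cfg.compute_psd:
        psd = spontaneous.compute_psd(cell.spontaneous)
        flag, peak = spontaneous.detect_oscillation(psd,
                                                    cfg.osc_ratio_threshold)
        row["fluctuation_ratio"] = psd.fluctuation_ratio
        row["osc_flag"] = flag
        row["osc_peak_freq_hz"] = peak
    return row


def _as_trialset(spike_train):
    from .synthetic import TrialSet
    return TrialSet([spike_train], spike_train.duration_s)


def run_pipeline(cfg: PipelineConfig) -> CohortReport:
    """Simulate a cohort and run every analysis stage on it.

    Deterministic given the stage seeds in ``cfg``.  Per stage, the report
    summarises each metric with its mean, bootstrap +-2 SE interval, and
    nested 50/80/100% percentile bands, plus the separable, responsive and
    oscillatory cell fractions; each metric is compared against the baseline
    stage by a KS test, Bonferroni corrected over the stage family.  A cell
    whose analysis fails is logged and skipped rather than aborting the run.
    """
    cohort = make_cohort(
        list(cfg.stages), cfg.cells_per_experiment, cfg.n_experiments,
        rows=cfg.rows, cols=cfg.cols, refresh_ms=cfg.refresh_ms,
        square_size_um=cfg.square_size_um, n_lags=cfg.n_lags,
        n_repeats=cfg.n_repeats, clip_s=cfg.clip_s,
        nonrepeat_s=cfg.nonrepeat_s,
        spont_s=cfg.spont_s if cfg.compute_psd else 60.0,
        simulate_spont=cfg.compute_psd,
    )
    rows, errors = [], []
    for cell in cohort.cells:
        try:
            rows.append(_analyze_cell(cell, cohort, cfg))
        except RetsigError as exc:   # partial report on per-cell failure
            errors.append((cell.unit_id, repr(exc)))
    per_cell = pd.DataFrame(rows)

    # per-experiment responsiveness thresholds -> responsive flags
    per_cell["is_responsive"] = False
    for exp, grp in per_cell.groupby("experiment"):
        thr = ln_model.responsiveness_threshold(
            grp["variance_mean_ratio"].to_numpy())
        per_cell.loc[grp.index, "is_responsive"] = (
            grp["variance_mean_ratio"] > thr)

    stage_order = [s.stage_label for s in cfg.stages]
    baseline = cfg.baseline_stage or stage_order[0]
    summary_rows = []
    boot_seed = int(cfg.stages[0].seed) % (2 ** 31)
    for stage in stage_order:
        grp = per_cell[per_cell["stage"] == stage]
        srow = {"stage": stage, "n_cells": len(grp),
                "separable_fraction": float(grp["is_separable"].mean()),
                "responsive_fraction": float(grp["is_responsive"].mean())}
        if "osc_flag" in grp:
            srow["oscillatory_fraction"] = float(grp["osc_flag"].mean())
        for metric in _COMPARED_METRICS:
            if metric not in grp:
                continue
            x = grp[metric].dropna().to_numpy()
            if x.size < 2:
                continue
            bs = bootstrap_mean(x, seed=boot_seed)
            srow[f"{metric}_mean"] = bs.mean
            srow[f"{metric}_lo2se"] = bs.lower
            srow[f"{metric}_hi2se"] = bs.upper
            for name, pct in _BAND_PCTS.items():
                srow[f"{metric}_{name}"] = float(np.percentile(x, pct))
        summary_rows.append(srow)
    per_stage = pd.DataFrame(summary_rows)

    comparisons = []
    others = [s for s in stage_order if s != baseline]
    family = len(others)
    for metric in _COMPARED_METRICS:
        if metric not in per_cell:
            continue
        base_x = per_cell.loc[per_cell["stage"] == baseline, metric].dropna()
        for stage in others:
            y = per_cell.loc[per_cell["stage"] == stage, metric].dropna()
            if base_x.size < 2 or y.size < 2:
                continue
            comp = ks_two_sample(base_x, y, metric, (baseline, stage))
            comp.p_adjusted = float(bonferroni([comp.p_raw], family)[0])
            comp.family_size = family
            comparisons.append(comp)
    return CohortReport(per_cell, per_stage, comparisons, errors, cfg)
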