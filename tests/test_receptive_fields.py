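"""Tests of STA computation, separability, RF metrics and autocorrelation."""

import dataclasses

import numpy as np
import pytest

import retsig
from retsig.errors import CoverageError, DegenerateInputError, EmptyResultError
from retsig.receptive_fields import STA


def _sta_from_volume(vol, refresh_ms=66.0, square_um=150.0):
    return STA(volume=np.asarray(vol, float), n_spikes=1,
               refresh_ms=refresh_ms, square_size_um=square_um)


class TestComputeSta:
    def test_single_spike_reproduces_preceding_frames(self):
        # direct-indexing oracle: with one spike in frame j the STA at lag k
        # is exactly frame j - k
        stim = retsig.make_checkerboard(5, 4, 30, 66.0, seed=2)
        j = 20
        t_spike = (j + 0.4) * 0.066
        spikes = retsig.SpikeTrain("u", np.array([t_spike]), stim.clip_duration_s)
        sta = retsig.compute_sta(spikes, stim, n_lags=6)
        for k in range(6):
            np.testing.assert_array_equal(sta.volume[:, :, k],
                                          stim.frames[:, :, j - k])

    def test_stimulus_independent_spikes_give_null_sta(self):
        stim = retsig.make_checkerboard(4, 4, 8000, 66.0, seed=3)
        rng = np.random.default_rng(4)
        times = np.sort(rng.uniform(1.0, stim.clip_duration_s - 1e-3, 3000))
        spikes = retsig.SpikeTrain("u", times, stim.clip_duration_s)
        sta = retsig.compute_sta(spikes, stim, n_lags=10)
        assert np.all(np.abs(sta.volume) < 4.0 / np.sqrt(sta.n_spikes))

    def test_on_cell_center_pixel_positive_at_peak(self, simulated_cell):
        sta, rf = simulated_cell["sta"], simulated_cell["rf"]
        r, c = int(round(rf.center_row)), int(round(rf.center_col))
        trace = sta.volume[r, c, :]
        assert trace[np.argmax(np.abs(trace))] > 0
        assert np.all(np.abs(sta.volume) <= 1.0)

    def test_early_spikes_dropped_and_counted(self):
        stim = retsig.make_checkerboard(3, 3, 50, 66.0, seed=5)
        times = np.array([0.01, 0.02, 2.0])
        spikes = retsig.SpikeTrain("u", times, stim.clip_duration_s)
        sta = retsig.compute_sta(spikes, stim, n_lags=10)
        assert sta.n_spikes == 1 and sta.n_dropped == 2

    def test_no_usable_spike_raises(self):
        stim = retsig.make_checkerboard(3, 3, 50, 66.0, seed=5)
        spikes = retsig.SpikeTrain("u", np.array([0.01]), stim.clip_duration_s)
        with pytest.raises(EmptyResultError):
            retsig.compute_sta(spikes, stim, n_lags=10)


class TestSvdDecompose:
    def test_exact_rank_one_input(self):
        rng = np.random.default_rng(6)
        spatial = rng.standard_normal((5, 5))
        temporal = rng.standard_normal(8)
        sep = retsig.svd_decompose(
            _sta_from_volume(spatial[:, :, None] * temporal[None, None, :]))
        assert sep.rank1_variance_fraction >= 1 - 1e-10
        r_s = np.corrcoef(sep.spatial.ravel(), spatial.ravel())[0, 1]
        r_t = np.corrcoef(sep.temporal, temporal)[0, 1]
        assert abs(r_s) == pytest.approx(1.0, abs=1e-9)
        assert abs(r_t) == pytest.approx(1.0, abs=1e-9)

    def test_two_orthogonal_components_give_half_fraction(self):
        # orthogonal spatial and temporal parts with equal weights: the two
        # singular values are equal, so the rank-1 pair captures exactly 1/2
        s1 = np.zeros((4, 4)); s1[0, 0] = 1.0
        s2 = np.zeros((4, 4)); s2[2, 2] = 1.0
        t1 = np.zeros(6); t1[0] = 1.0
        t2 = np.zeros(6); t2[3] = 1.0
        vol = s1[:, :, None] * t1 + s2[:, :, None] * t2
        sep = retsig.svd_decompose(_sta_from_volume(vol))
        assert sep.rank1_variance_fraction == pytest.approx(0.5, abs=1e-12)

    def test_energy_conservation(self, simulated_cell):
        sep = simulated_cell["sep"]
        sta = simulated_cell["sta"]
        frob2 = np.sum(sta.volume ** 2)
        assert np.sum(sep.singular_values ** 2) == pytest.approx(
            frob2, rel=1e-8)

    def test_all_zero_sta_rejected(self):
        with pytest.raises(DegenerateInputError):
            retsig.svd_decompose(_sta_from_volume(np.zeros((3, 3, 4))))

    def test_polarity_flips_with_ground_truth(self, long_checkerboard,
                                              default_rf, template_crf):
        off_rf = dataclasses.replace(default_rf, polarity="OFF")
        spikes = retsig.simulate_ln_spike_train(
            long_checkerboard, off_rf, template_crf, seed=7)
        sep = retsig.svd_decompose(
            retsig.compute_sta(spikes, long_checkerboard, 15))
        assert sep.polarity == "OFF"

    def test_on_cell_polarity(self, simulated_cell):
        assert simulated_cell["sep"].polarity == "ON"


class TestClassifySeparable:
    @pytest.mark.parametrize("fraction,expected",
                             [(0.61, True), (0.60, False), (1.0, True)])
    def test_strict_threshold(self, fraction, expected):
        sep = retsig.SeparableRF(np.ones((2, 2)), np.ones(3), np.ones(3),
                                 fraction, "ON", False)
        assert retsig.classify_separable(sep) is expected


class TestGaussianFit:
    @staticmethod
    def _gaussian_patch(sigma=2.0, rows=21, cols=21, amp=1.0):
        r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return amp * np.exp(-((r - 10) ** 2 + (c - 10) ** 2) / (2 * sigma ** 2))

    def test_noiseless_recovery_and_area(self):
        # closed-form oracle: sigma 2 squares x 150 um -> 300 um;
        # 2-SD contour area = pi * 600 * 600
        fit = retsig.fit_rf_gaussian(self._gaussian_patch(2.0), 150.0)
        assert fit.sigma_major_um == pytest.approx(300.0, rel=0.01)
        assert fit.sigma_minor_um == pytest.approx(300.0, rel=0.01)
        assert fit.rf_area_um2 == pytest.approx(np.pi * 600 * 600, rel=0.02)

    def test_isotropic_input_gives_equal_sigmas(self):
        fit = retsig.fit_rf_gaussian(self._gaussian_patch(1.5), 150.0)
        assert fit.sigma_major / fit.sigma_minor == pytest.approx(1.0, abs=0.01)

    def test_grid_scale_consistency(self):
        # the same physical RF sampled on mesopic (150 um) vs photopic
        # (75 um, twice the squares) grids must report consistent areas
        mesopic = retsig.fit_rf_gaussian(self._gaussian_patch(2.0, 21, 21), 150.0)
        photopic = retsig.fit_rf_gaussian(
            self._gaussian_patch(4.0, 42, 42), 75.0)
        assert mesopic.rf_area_um2 == pytest.approx(photopic.rf_area_um2,
                                                    rel=0.02)

    def test_zero_filter_rejected(self):
        with pytest.raises(ValueError):
            retsig.fit_rf_gaussian(np.zeros((5, 5)), 150.0)


class TestTemporalMetrics:
    def test_hand_computed_crossing(self):
        # crossing midway between samples 1 and 2 of [+1,+.5,-.5,-1] at 66 ms
        tm = retsig.temporal_metrics(np.array([1.0, 0.5, -0.5, -1.0]), 66.0,
                                     noise_sd=0.0)
        assert tm.is_biphasic
        assert tm.time_to_zero_ms == pytest.approx(99.0)

    def test_monophasic_filter(self):
        tm = retsig.temporal_metrics(np.array([0.2, 1.0, 0.4, 0.1, 0.0, 0.0]),
                                     66.0)
        assert not tm.is_biphasic and tm.time_to_zero_ms is None

    def test_recovered_crossing_matches_analytic(self, simulated_cell):
        tm = retsig.temporal_metrics(simulated_cell["sep"].temporal, 66.0)
        assert tm.is_biphasic
        assert tm.time_to_zero_ms == pytest.approx(
            simulated_cell["rf"].zero_crossing_ms, abs=33.0)

    def test_small_second_lobe_not_biphasic(self):
        w = np.array([1.0, 0.5, -0.01, 0.0, 0.0])
        tm = retsig.temporal_metrics(w, 66.0, noise_sd=0.05)
        assert not tm.is_biphasic


class TestStaSnr:
    def test_noiseless_sta_is_capped(self, default_rf):
        # compact-support spatial filter: pixels far from the centre are
        # exactly zero, so far_sd collapses to 0 and the snr is capped
        r, c = np.meshgrid(np.arange(15), np.arange(15), indexing="ij")
        d2 = (r - 7.0) ** 2 + (c - 7.0) ** 2
        spatial = np.exp(-d2 / (2 * 1.2 ** 2)) * (d2 <= 9.0)
        temporal = default_rf.temporal_filter(15, 66.0)
        sta = _sta_from_volume(spatial[:, :, None] * temporal)
        sep = retsig.svd_decompose(sta)
        fit = retsig.fit_rf_gaussian(sep.spatial, 150.0)
        res = retsig.sta_snr(sta, fit)
        assert res.capped and res.snr >= 1e6

    def test_noise_scaling_halves_snr(self, default_rf):
        # snr is proportional to 1/far_sd, so doubling additive pixel noise
        # at fixed signal halves it (Monte-Carlo average); compact-support
        # signal so the far pixels carry noise only
        r, c = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        d2 = (r - 8.0) ** 2 + (c - 8.0) ** 2
        spatial = np.exp(-d2 / (2 * 1.2 ** 2)) * (d2 <= 9.0)
        temporal = default_rf.temporal_filter(15, 66.0)
        vol = spatial[:, :, None] * temporal
        vol /= np.linalg.norm(vol)
        sep = retsig.svd_decompose(_sta_from_volume(vol))
        fit = retsig.fit_rf_gaussian(sep.spatial, 150.0)
        rng = np.random.default_rng(12)
        ratios = []
        for _ in range(200):
            noise = rng.standard_normal(vol.shape)
            s1 = retsig.sta_snr(_sta_from_volume(vol + 0.002 * noise), fit)
            s2 = retsig.sta_snr(_sta_from_volume(vol + 0.004 * noise), fit)
            ratios.append(s1.snr / s2.snr)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.1)

    def test_pure_noise_sta_has_low_snr(self, default_rf):
        # Monte-Carlo null: with no signal the snr concentrates near its
        # order-statistic expectation, below 3 for almost all draws
        vol = default_rf.render(16, 16, 15, 66.0)
        sep = retsig.svd_decompose(_sta_from_volume(vol))
        fit = retsig.fit_rf_gaussian(sep.spatial, 150.0)
        rng = np.random.default_rng(13)
        snrs = [
            retsig.sta_snr(
                _sta_from_volume(rng.standard_normal(vol.shape)), fit).snr
            for _ in range(1000)
        ]
        assert np.mean(np.asarray(snrs) < 3.0) >= 0.99

    def test_rf_filling_frame_raises(self):
        vol = np.ones((4, 4, 3))
        fit = retsig.GaussianFit(2, 2, 300, 300, 600, 600, 4, 4, 0.0, 1.0,
                                 0.0, 1.0, 0.0)
        with pytest.raises(CoverageError):
            retsig.sta_snr(_sta_from_volume(vol), fit)


class TestSpikeAutocorrelation:
    def test_poisson_acf_flat(self):
        sp = retsig.simulate_spontaneous(1200.0, 10.0, seed=14)
        lags, acf = retsig.spike_autocorrelation(sp, bin_ms=10.0,
                                                 max_lag_ms=400.0)
        n_pairs = sp.times.size ** 2 / (sp.duration_s / 0.01)
        se = 1.0 / np.sqrt(n_pairs)
        assert np.all(np.abs(acf - 1.0) < 4 * se)

    def test_five_hz_modulation_peaks_at_200ms_multiples(self):
        sp = retsig.simulate_spontaneous(1200.0, 20.0, 5.0, 0.9, seed=15)
        lags, acf = retsig.spike_autocorrelation(sp, bin_ms=10.0,
                                                 max_lag_ms=450.0)
        peak_lag = lags[np.argmax(acf)]
        assert peak_lag == pytest.approx(200.0, abs=10.0) or \
            peak_lag == pytest.approx(400.0, abs=10.0)
        # trough near the half period
        trough_lag = lags[np.argmin(acf)]
        assert trough_lag % 200.0 == pytest.approx(100.0, abs=20.0)

    def test_refractory_first_bin_suppressed(self):
        rng = np.random.default_rng(16)
        # Poisson with 4 ms dead time
        isi = rng.exponential(1 / 30.0, 20000) + 0.004
        times = np.cumsum(isi)
        sp = retsig.SpikeTrain("u", times[times < 600.0], 600.0)
        lags, acf = retsig.spike_autocorrelation(sp, bin_ms=2.0,
                                                 max_lag_ms=40.0)
        assert acf[0] < 0.25
        assert np.mean(acf[-5:]) > 0.7


class TestOnOffSymmetry:
    def test_off_cell_metrics_match_on_cell(self, long_checkerboard,
                                            default_rf, template_crf,
                                            simulated_cell):
        import dataclasses

        off_rf = dataclasses.replace(default_rf, polarity="OFF")
        spikes = retsig.simulate_ln_spike_train(
            long_checkerboard, off_rf, template_crf, seed=7)
        sta = retsig.compute_sta(spikes, long_checkerboard, 15)
        sep = retsig.svd_decompose(sta)
        on_sep = simulated_cell["sep"]
        tm_on = retsig.temporal_metrics(on_sep.temporal, 66.0)
        tm_off = retsig.temporal_metrics(sep.temporal, 66.0)
        assert tm_off.time_to_zero_ms == pytest.approx(
            tm_on.time_to_zero_ms, abs=33.0)
        fit_on = retsig.fit_rf_gaussian(on_sep.spatial, 150.0)
        fit_off = retsig.fit_rf_gaussian(sep.spatial, 150.0)
        assert fit_off.rf_area_um2 == pytest.approx(fit_on.rf_area_um2,
                                                    rel=0.2)
        snr_on = retsig.sta_snr(simulated_cell["sta"], fit_on).snr
        snr_off = retsig.sta_snr(sta, fit_off).snr
        assert snr_off == pytest.approx(snr_on, rel=0.35)
        assert snr_off > 0
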