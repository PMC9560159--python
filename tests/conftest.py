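import numpy as np
import pytest

import retsig


@pytest.fixture(scope="session")
def default_rf():
    return retsig.GroundTruthRF(
        center_row=6.0, center_col=5.0, sigma_center=1.2, sigma_surround=2.5,
        surround_weight=0.15, tau1_ms=80.0, tau2_ms=160.0, lobe_ratio=0.6,
    )


@pytest.fixture(scope="session")
def template_crf():
    return retsig.default_crf_template()


@pytest.fixture(scope="session")
def long_checkerboard():
    """~30 min of 66 ms mesopic-style checkerboard on a 12x12 grid."""
    n_frames = int(1800 * 1000 / 66)
    return retsig.make_checkerboard(12, 12, n_frames, 66.0, 150.0, seed=101)


@pytest.fixture(scope="session")
def simulated_cell(long_checkerboard, default_rf, template_crf):
    """One LN cell driven by the 30 min checkerboard, with its STA and SVD."""
    spikes = retsig.simulate_ln_spike_train(
        long_checkerboard, default_rf, template_crf, seed=7)
    sta = retsig.compute_sta(spikes, long_checkerboard, n_lags=15)
    sep = retsig.svd_decompose(sta)
    return {"stim": long_checkerboard, "rf": default_rf, "crf": template_crf,
            "spikes": spikes, "sta": sta, "sep": sep}


@pytest.fixture(scope="session")
def repeat_trials(default_rf, template_crf):
    """200 repeats of a 10 s checkerboard clip, as in the repeat protocol."""
    clip = retsig.make_checkerboard(10, 10, 151, 66.0, 150.0, seed=55)
    trials = retsig.simulate_ln_trials(
        clip, default_rf, template_crf, n_trials=200, seed=56)
    return {"clip": clip, "trials": trials}
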