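import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnirs_vhdr.events import MOCK, STIM, generate_event_schedule
from fnirs_vhdr.metrics import (
    best_channel_response,
    block_average,
    channel_average_response,
    compute_subject_response,
    epoch_trials,
    extract_peak,
    hemisphere_peaks,
    laterality_index,
    subject_metrics_table,
)
from fnirs_vhdr.recording import hb_from_ohb_dhb
from fnirs_vhdr.simulate import simulate_subject, td_default_config


@pytest.fixture(scope="module")
def noiseless_epochs(noiseless_subject):
    rec, _ = noiseless_subject
    return epoch_trials(rec)


class TestEpoching:
    def test_twenty_rows_per_condition(self, noiseless_epochs):
        assert noiseless_epochs.n_trials(STIM) == 20
        assert noiseless_epochs.n_trials(MOCK) == 20

    def test_constant_recording_epochs_to_zero(self, montage, short_schedule):
        n_t = int((short_schedule.total_duration_s + 10) * 10.2)
        const = np.full((montage.n_channels, n_t), 7e-6)
        rec = hb_from_ohb_dhb(10.2, const, const, montage, short_schedule.shifted(5.0))
        ep = epoch_trials(rec)
        for key, arr in ep.data.items():
            assert np.allclose(arr, 0.0, atol=1e-18)

    def test_ramp_minus_baseline_mean(self, montage, short_schedule):
        fs = 10.2
        n_t = int((short_schedule.total_duration_s + 10) * fs)
        ramp = np.tile(np.arange(n_t, dtype=float), (montage.n_channels, 1))
        rec = hb_from_ohb_dhb(fs, ramp, np.zeros_like(ramp), montage, short_schedule.shifted(5.0))
        ep = epoch_trials(rec)
        arr = ep.data[(short_schedule.trials[0].condition, "OHb")]
        trial0 = arr[0, 0]
        onset = short_schedule.trials[0].onset_s + 5.0
        start = int(round((onset - ep.pre_s) * fs))
        expected_raw = np.arange(start, start + trial0.size, dtype=float)
        bmask = (ep.times >= -2.0 - 1e-9) & (ep.times <= 1e-9)
        assert np.allclose(trial0, expected_raw - expected_raw[bmask].mean())

    def test_out_of_bounds_trials_dropped(self, montage):
        sched = generate_event_schedule(3, 0, 5, 10, seed=0)  # onsets 0,15,30
        n_t = int(50 * 10.2)
        rec = hb_from_ohb_dhb(10.2, np.zeros((22, n_t)), np.zeros((22, n_t)), montage, sched)
        ep = epoch_trials(rec)  # first trial lacks 2 s of pre-window
        assert ep.n_trials(STIM) == 2

    def test_all_trials_outside_is_error(self, montage):
        sched = generate_event_schedule(1, 0, 5, 10, seed=0)
        rec = hb_from_ohb_dhb(10.2, np.zeros((22, 50)), np.zeros((22, 50)), montage, sched)
        with pytest.raises(ValueError):
            epoch_trials(rec)


class TestBlockAverage:
    def test_identical_trials(self, montage, short_schedule, noiseless_config):
        rec, _ = simulate_subject(montage, short_schedule, noiseless_config, seed=0)
        ep = epoch_trials(rec)
        mean, sem = block_average(ep, STIM)
        single = ep.data[(STIM, "OHb")][:, 0, :]
        # noiseless trials are near-identical; sem is tiny relative to peak
        assert np.allclose(mean, single, atol=0.05 * np.abs(single).max())

    def test_hand_sem(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        sem = vals.std(ddof=1) / 2.0
        assert sem == pytest.approx(0.6455, abs=1e-4)
        assert vals.mean() == pytest.approx(2.5)

    def test_plus_minus_cancel(self, montage, short_schedule):
        # two trials with equal and opposite deviations average to zero
        fs = 10.2
        sched = generate_event_schedule(2, 0, 5, 10, seed=1).shifted(5.0)
        n_t = int(45 * fs)
        x = np.zeros((22, n_t))
        i0, i1 = int(5 * fs), int(20 * fs)
        bump = np.sin(np.linspace(0, np.pi, 30))
        x[:, i0 + 30: i0 + 60] = bump
        x[:, i1 + 30: i1 + 60] = -bump
        rec = hb_from_ohb_dhb(fs, x, np.zeros_like(x), montage, sched)
        mean, _ = block_average(epoch_trials(rec), STIM)
        assert np.abs(mean).max() < 1e-9

    def test_zero_trials_error(self, noiseless_epochs):
        with pytest.raises(ValueError):
            block_average(noiseless_epochs, "NEITHER")


class TestPeaks:
    def test_noiseless_amplitude_and_latency(self, noiseless_epochs, noiseless_subject):
        _, truth = noiseless_subject
        mean, _ = block_average(noiseless_epochs, STIM)
        amp, lat = extract_peak(mean[0], noiseless_epochs.times, "OHb")
        assert amp == pytest.approx(truth.ohb_amp[0], rel=0.05)
        assert 4.0 < lat < 12.0

    def test_dhb_sign_symmetry(self, noiseless_epochs):
        mean, _ = block_average(noiseless_epochs, STIM)
        amp_o, lat_o = extract_peak(mean[0], noiseless_epochs.times, "OHb")
        amp_d, lat_d = extract_peak(-mean[0], noiseless_epochs.times, "DHb")
        assert amp_d == pytest.approx(-amp_o)
        assert lat_d == lat_o

    def test_tie_breaks_to_earliest(self):
        times = np.arange(0, 15, 0.5)
        trace = np.zeros(times.size)
        trace[times == 5.0] = 1.0
        trace[times == 8.0] = 1.0
        _, lat = extract_peak(trace, times, "OHb", (0, 15))
        assert lat == 5.0

    def test_empty_window_error(self):
        with pytest.raises(ValueError):
            extract_peak(np.zeros(10), np.arange(10.0), "OHb", (20, 25))


class TestChannelSummaries:
    def test_identical_channels_equal_single(self, montage, short_schedule, noiseless_config):
        import dataclasses

        cfg = dataclasses.replace(noiseless_config, lateralization=1.0)
        rec, truth = simulate_subject(montage, short_schedule, cfg, seed=0)
        ep = epoch_trials(rec)
        avg = channel_average_response(ep, STIM)
        mean, _ = block_average(ep, STIM)
        single_amp, _ = extract_peak(mean[0], ep.times, "OHb")
        assert avg["OHb"][0] == pytest.approx(single_amp)

    def test_scaled_channels_average(self, montage, short_schedule):
        fs = 10.2
        sched = generate_event_schedule(2, 0, 5, 10, seed=1).shifted(5.0)
        n_t = int(45 * fs)
        base = np.zeros(n_t)
        i0 = int(5 * fs)
        base[i0 + 40: i0 + 70] = np.sin(np.linspace(0, np.pi, 30))
        base[int(20 * fs) + 40: int(20 * fs) + 70] = np.sin(np.linspace(0, np.pi, 30))
        x = np.zeros((22, n_t))
        x[0] = base
        x[1] = 3 * base
        rec = hb_from_ohb_dhb(fs, x, np.zeros_like(x), montage, sched)
        ep = epoch_trials(rec)
        ep.usable[:] = False
        ep.usable[[0, 1]] = True
        avg = channel_average_response(ep, STIM)
        peak = np.sin(np.linspace(0, np.pi, 30)).max()
        assert avg["OHb"][0] == pytest.approx(2.0 * peak, rel=1e-6)

    def test_best_channel_unique_maximum(self, noiseless_epochs, noiseless_subject):
        _, truth = noiseless_subject
        best_id, peaks = best_channel_response(noiseless_epochs, STIM)
        expect = noiseless_epochs.montage.channel_ids[int(np.argmax(truth.ohb_amp))]
        assert best_id == expect

    def test_best_channel_tie_lowest_index(self, montage, short_schedule, noiseless_config):
        import dataclasses

        cfg = dataclasses.replace(noiseless_config, lateralization=1.0)
        rec, _ = simulate_subject(montage, short_schedule, cfg, seed=0)
        ep = epoch_trials(rec)
        best_id, _ = best_channel_response(ep, STIM)
        assert best_id == montage.channel_ids[0]

    def test_best_at_least_channel_average(self, montage, short_schedule):
        cfg = td_default_config()
        for seed in range(10):
            rec, _ = simulate_subject(montage, short_schedule, cfg, seed=seed)
            ep = epoch_trials(rec)
            avg = channel_average_response(ep, STIM)["OHb"][0]
            _, best = best_channel_response(ep, STIM)
            assert best["OHb"][0] >= avg - 1e-15


class TestHemispheres:
    def test_symmetric_signals_equal_peaks(self, montage, short_schedule, noiseless_config):
        import dataclasses

        cfg = dataclasses.replace(noiseless_config, lateralization=1.0)
        rec, _ = simulate_subject(montage, short_schedule, cfg, seed=0)
        pl, pr = hemisphere_peaks(epoch_trials(rec), STIM)
        assert pl == pytest.approx(pr)

    def test_lateralized_simulation(self, montage, short_schedule, noiseless_config):
        import dataclasses

        cfg = dataclasses.replace(noiseless_config, lateralization=3.0)
        rec, _ = simulate_subject(montage, short_schedule, cfg, seed=0)
        pl, pr = hemisphere_peaks(epoch_trials(rec), STIM)
        assert pr == pytest.approx(3 * pl, rel=0.02)

    def test_mean_of_per_channel_maxima(self, montage, short_schedule):
        fs = 10.2
        sched = generate_event_schedule(1, 0, 5, 10, seed=1).shifted(5.0)
        n_t = int(30 * fs)
        bump = np.zeros(n_t)
        bump[int(5 * fs) + 40: int(5 * fs) + 70] = np.sin(np.linspace(0, np.pi, 30))
        left = montage.channel_indices("left")
        x = np.zeros((22, n_t))
        x[left[0]] = 1.0 * bump
        x[left[1]] = 3.0 * bump
        x[montage.channel_indices("right")[0]] = 1.0 * bump
        rec = hb_from_ohb_dhb(fs, x, np.zeros_like(x), montage, sched)
        ep = epoch_trials(rec)
        ep.usable[:] = False
        ep.usable[[left[0], left[1], montage.channel_indices("right")[0]]] = True
        pl, _pr = hemisphere_peaks(ep, STIM)
        peak = np.sin(np.linspace(0, np.pi, 30)).max()
        assert pl == pytest.approx(2.0 * peak, rel=1e-6)

    def test_missing_hemisphere_error(self, noiseless_epochs):
        ep = noiseless_epochs
        saved = ep.usable.copy()
        try:
            for i in ep.montage.channel_indices("left"):
                ep.usable[i] = False
            with pytest.raises(ValueError, match="left"):
                hemisphere_peaks(ep, STIM)
        finally:
            ep.usable[:] = saved


class TestLateralityIndex:
    def test_printed_formula_example(self):
        assert laterality_index(2e-5, 6e-5) == pytest.approx(-0.5)

    def test_boundaries(self):
        assert laterality_index(1.0, 1.0) == 0.0
        assert laterality_index(1.0, 0.0) == 1.0

    def test_zero_denominator_is_explicit_error(self):
        with pytest.raises(ZeroDivisionError):
            laterality_index(1.0, -1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.floats(1e-7, 1e-3), b=st.floats(1e-7, 1e-3),
        c=st.floats(0.1, 100.0),
    )
    def test_antisymmetry_and_scale_invariance(self, a, b, c):
        li = laterality_index(a, b)
        assert laterality_index(b, a) == pytest.approx(-li, abs=1e-12)
        assert laterality_index(c * a, c * b) == pytest.approx(li, rel=1e-9)
        assert -1.0 <= li <= 1.0


def test_subject_metrics_table_shape(noiseless_subject):
    rec, _ = noiseless_subject
    table = subject_metrics_table("S1", "TD", rec)
    assert set(table.columns) == {
        "subject_id", "group", "condition", "chromophore", "metric", "value"}
    stim = table[table.condition == STIM]
    assert set(stim.metric) == {
        "avg_amp", "avg_lat", "best_amp", "best_lat", "peak_left", "peak_right", "LI"}
    li = stim[stim.metric == "LI"]["value"].iloc[0]
    assert li == pytest.approx(-0.2, abs=0.02)  # lambda = 1.5


def test_mock_amplitude_zero_in_noiseless_null(montage, short_schedule, noiseless_config):
    """With zero amplitude and zero noise the mock-condition amplitude is
    exactly zero (a window-max statistic is positively biased once any noise
    is present, so the exact-zero check is the meaningful null case)."""
    import dataclasses

    cfg = dataclasses.replace(noiseless_config, ohb_amplitude=0.0)
    rec, _ = simulate_subject(montage, short_schedule, cfg, seed=0)
    ep = epoch_trials(rec)
    assert channel_average_response(ep, MOCK)["OHb"][0] == 0.0


def test_mock_amplitude_small_at_default_snr(montage, schedule):
    """At default SNR the mock response is a small fraction of the stimulus
    response for every simulated subject."""
    cfg = td_default_config()
    for seed in range(5):
        rec, _ = simulate_subject(montage, schedule, cfg, seed=seed)
        ep = epoch_trials(rec)
        stim_amp = channel_average_response(ep, STIM)["OHb"][0]
        mock_amp = channel_average_response(ep, MOCK)["OHb"][0]
        assert mock_amp < 0.25 * stim_amp
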