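import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from fnirs_vhdr.events import STIM
from fnirs_vhdr.montage import LEFT, RIGHT, Channel, MontageLayout
from fnirs_vhdr.simulate import (
    ClinicalModel,
    KernelParams,
    canonical_response_kernel,
    inject_motion_artifacts,
    simulate_cohort,
    simulate_subject,
    td_default_config,
)


class TestKernel:
    def test_causal_and_unit_peak(self):
        t = np.arange(0, 30, 0.01)
        k = canonical_response_kernel(t)
        assert k[0] == 0.0
        assert k.max() == pytest.approx(1.0, abs=1e-5)

    def test_peak_latency_physiological(self):
        t = np.arange(0, 30, 0.001)
        k = canonical_response_kernel(t)
        assert 4.0 <= t[np.argmax(k)] <= 8.0

    def test_single_maximum_then_decay(self):
        t = np.arange(0, 30, 0.01)
        k = canonical_response_kernel(t)
        peak = np.argmax(k)
        assert np.all(np.diff(k[: peak + 1]) >= -1e-12)
        assert abs(k[-1]) < 0.05

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            canonical_response_kernel(np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            canonical_response_kernel(np.array([-1.0, 0.0, 1.0]))


class TestSimulateSubject:
    def test_noiseless_peak_equals_amplitude(self, montage, schedule, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, lateralization=1.0)
        rec, truth = simulate_subject(montage, schedule, cfg, seed=0)
        # per-channel raw series maximum matches the configured amplitude
        assert rec.ohb.max() == pytest.approx(cfg.ohb_amplitude, rel=1e-6)
        assert np.allclose(truth.ohb_amp, cfg.ohb_amplitude)

    def test_seed_determinism_bit_identical(self, montage, schedule):
        cfg = td_default_config()
        a, _ = simulate_subject(montage, schedule, cfg, seed=11)
        b, _ = simulate_subject(montage, schedule, cfg, seed=11)
        assert np.array_equal(a.ohb, b.ohb)
        assert np.array_equal(a.dhb, b.dhb)

    def test_lateralization_three_gives_li_minus_half(self, montage, schedule, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, lateralization=3.0)
        _, truth = simulate_subject(montage, schedule, cfg, seed=0)
        assert truth.li == pytest.approx(-0.5)
        assert truth.peak_right == pytest.approx(3 * truth.peak_left)

    def test_thb_is_exact_sum(self, noisy_subject):
        rec, _ = noisy_subject
        assert np.max(np.abs(rec.thb - (rec.ohb + rec.dhb))) < 1e-12

    def test_mock_trials_evoke_nothing(self, montage, noiseless_config):
        from fnirs_vhdr.events import generate_event_schedule

        mock_only = generate_event_schedule(0, 10, 5, 10, seed=0)
        rec, _ = simulate_subject(montage, mock_only, noiseless_config, seed=0)
        assert np.abs(rec.ohb).max() == 0.0

    def test_li_antisymmetric_under_hemisphere_swap(self, schedule, noiseless_config, montage):
        """Relabelling each channel's hemisphere while keeping the simulated
        amplitudes fixed negates the ground-truth laterality index."""
        _, truth = simulate_subject(montage, schedule, noiseless_config, seed=5)
        left = montage.channel_indices(LEFT)
        right = montage.channel_indices(RIGHT)
        swapped_left = float(np.mean(truth.ohb_amp[right]))
        swapped_right = float(np.mean(truth.ohb_amp[left]))
        li_swapped = (swapped_left - swapped_right) / (swapped_left + swapped_right)
        assert li_swapped == pytest.approx(-truth.li)

    def test_dhb_amplitude_ratio_and_sign(self, noiseless_subject):
        _, truth = noiseless_subject
        assert np.all(truth.dhb_amp < 0)
        assert np.allclose(truth.dhb_amp, -truth.ohb_amp / 3.0)


class TestArtifacts:
    def test_zero_rate_is_noop(self, rng):
        od = rng.normal(size=(4, 2, 500))
        out, events = inject_motion_artifacts(od, 10.2, 0.0, 4.0, 2.0, seed=1)
        assert np.array_equal(out, od)
        assert events == []

    def test_seed_determinism(self, rng):
        od = rng.normal(size=(4, 2, 2000))
        a, ev_a = inject_motion_artifacts(od, 10.2, 2.0, 4.0, 2.0, seed=5)
        b, ev_b = inject_motion_artifacts(od, 10.2, 2.0, 4.0, 2.0, seed=5)
        assert np.array_equal(a, b)
        assert [e.sample for e in ev_a] == [e.sample for e in ev_b]

    def test_poisson_event_rate(self):
        """Mean event count over 10-minute recordings matches rate * duration."""
        n_t = int(600 * 10.2)
        od = np.zeros((1, 2, n_t))
        counts = [
            len(inject_motion_artifacts(od, 10.2, 1.2, 4.0, 2.0, seed=s)[1])
            for s in range(200)
        ]
        assert np.mean(counts) == pytest.approx(12.0, abs=3 * np.sqrt(12 / 200))


class TestCohort:
    def test_cohort_structure(self):
        subjects, clinical = simulate_cohort(13, 12, seed=0)
        assert len(subjects) == 25
        assert sum(1 for s in subjects if s.group == "TD") == 13
        # clinical rows only for the ASD group
        assert len(clinical) == 12
        assert all(sid.startswith("ASD") for sid in clinical["subject_id"])

    def test_noise_free_clinical_model_is_perfectly_monotone(self):
        model = ClinicalModel(aq_noise_sd=0.0)
        subjects, clinical = simulate_cohort(2, 12, clinical_model=model, seed=1)
        true_li = [s.truth.li for s in subjects if s.group == "ASD"]
        rho, _ = spearmanr(true_li, clinical["AQ_tot"])
        assert rho == pytest.approx(1.0)

    def test_master_seed_determinism(self):
        a, ca = simulate_cohort(3, 3, seed=42)
        b, cb = simulate_cohort(3, 3, seed=42)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.recording.ohb, sb.recording.ohb)
        assert ca.equals(cb)

    def test_requires_subjects(self):
        with pytest.raises(ValueError):
            simulate_cohort(0, 5)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        dataclasses.replace(td_default_config(), lateralization=-1.0)
    with pytest.raises(ValueError):
        dataclasses.replace(td_default_config(), white_sd=-1e-9)
    with pytest.raises(ValueError):
        dataclasses.replace(td_default_config(), sampling_rate=0.0)


def test_kernel_params_configurable():
    t = np.arange(0, 30, 0.01)
    slow = canonical_response_kernel(t, KernelParams(peak_delay_s=7.0))
    fast = canonical_response_kernel(t, KernelParams(peak_delay_s=4.0))
    assert t[np.argmax(slow)] > t[np.argmax(fast)]
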