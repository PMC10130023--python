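"""Synthetic cohort generator: morphology, placement, confounds, reproducibility."""

import numpy as np
import pytest
from scipy.signal import welch

from focalspike.errors import CapacityError
from focalspike.montage import CANONICAL_CHANNELS, REGION_CHANNELS, channel_index
from focalspike.recording import Recording
from focalspike.synth import (
    SynthCohortConfig,
    default_duration_sampler,
    draw_ied_count,
    inject_eye_blinks,
    inject_ieds,
    make_background,
    make_spike_wave,
    simulate_cohort,
)
from conftest import scaled_cohort_config


class TestBackground:
    def test_shape_and_determinism(self):
        rec1 = make_background(60, 200, seed=7)
        rec2 = make_background(60, 200, seed=7)
        assert rec1.signal.shape == (19, 12000)
        np.testing.assert_array_equal(rec1.signal, rec2.signal)

    def test_alpha_raises_posterior_10hz_power(self):
        with_alpha = make_background(60, 200, alpha_amplitude_uV=20, seed=3)
        without = make_background(60, 200, alpha_amplitude_uV=0, seed=3)
        o1 = channel_index("O1")
        for rec in (with_alpha, without):
            assert rec.signal.shape == (19, 12000)
        f, p_with = welch(with_alpha.signal[o1], fs=200, nperseg=1024)
        _, p_without = welch(without.signal[o1], fs=200, nperseg=1024)
        band = (f > 8) & (f < 12)
        assert p_with[band].max() > p_without[band].max()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_background(0, 200)
        with pytest.raises(ValueError):
            make_background(60, -1)

    def test_background_rms_scale(self):
        rec = make_background(30, 200, alpha_amplitude_uV=0, background_rms_uV=15,
                              common_mode_frac=0.0, seed=0)
        rms = rec.signal.std(axis=1)
        assert np.all(rms > 10) and np.all(rms < 20)


class TestSpikeWave:
    def test_duration_and_length(self):
        tpl = make_spike_wave(200, 0.07, 0.38, 100)
        assert tpl.size == 90  # 0.45 s at 200 Hz
        assert np.isclose(np.abs(tpl).max(), 100)

    def test_spike_only(self):
        tpl = make_spike_wave(200, 0.07, 0.0, 50)
        assert tpl.size == 14
        assert np.isclose(np.abs(tpl).max(), 50)

    def test_wave_opposes_spike_polarity(self):
        tpl = make_spike_wave(200, 0.07, 0.38, 100)
        n_spike = round(0.07 * 200)
        spike_peak = tpl[:n_spike][np.abs(tpl[:n_spike]).argmax()]
        wave_integral = tpl[n_spike:].sum()
        assert np.sign(spike_peak) == -np.sign(wave_integral)
        assert spike_peak < 0  # surface-negative focus by default

    @pytest.mark.parametrize("spike_dur", [0.01, 0.3])
    def test_spike_duration_bounds(self, spike_dur):
        with pytest.raises(ValueError):
            make_spike_wave(200, spike_dur, 0.3, 100)


class TestInjectIeds:
    def test_boundary_contract(self):
        rec = make_background(60, 200, seed=1)
        _, ann = inject_ieds(rec, "occipital", 5, min_gap_s=2.0, seed=1)
        assert len(ann) == 5
        for ev in ann:
            assert ev.onset_s >= 0.75
            assert ev.offset_s <= 59.25
            assert ev.region == "occipital"

    def test_zero_events_is_identity(self):
        rec = make_background(30, 200, seed=2)
        out, ann = inject_ieds(rec, "frontal", 0, seed=2)
        assert len(ann) == 0
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_min_gap_respected(self):
        rec = make_background(60, 200, seed=4)
        _, ann = inject_ieds(rec, "temporal", 6, min_gap_s=2.0, seed=4)
        events = sorted(ann, key=lambda e: e.onset_s)
        for prev, nxt in zip(events, events[1:]):
            assert nxt.onset_s - prev.offset_s >= 2.0 - 1e-9

    def test_focus_rms_exceeds_background(self):
        rec = make_background(60, 200, seed=5)
        out, ann = inject_ieds(rec, "occipital", 8, seed=5, amplitude_uV=100)
        o1 = out.channel("O1")
        fs = 200
        inside = np.concatenate(
            [o1[int(ev.onset_s * fs):int(ev.offset_s * fs)] for ev in ann]
        )
        mask = np.ones(o1.size, bool)
        for ev in ann:
            mask[int(ev.onset_s * fs):int(ev.offset_s * fs)] = False
        outside = o1[mask][: inside.size]
        assert np.sqrt((inside**2).mean()) > np.sqrt((outside**2).mean())

    def test_infeasible_packing_reports_capacity(self):
        rec = make_background(20, 200, seed=6)
        with pytest.raises(CapacityError, match="at most"):
            inject_ieds(rec, "occipital", 50, min_gap_s=2.0, seed=6)


class TestEyeBlinks:
    def test_zero_rate_identity(self):
        rec = make_background(30, 200, seed=7)
        out = inject_eye_blinks(rec, 0.0, seed=7)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_frontal_variance_increases(self):
        rec = make_background(60, 200, seed=3)
        out = inject_eye_blinks(rec, 10.0, seed=3)
        fp1 = channel_index("Fp1")
        assert out.signal[fp1].var() > rec.signal[fp1].var()

    def test_blink_energy_focal_to_frontopolar(self):
        rec = make_background(60, 200, seed=9)
        out = inject_eye_blinks(rec, 10.0, seed=9)
        added = out.signal - rec.signal
        e_fp1 = (added[channel_index("Fp1")] ** 2).sum()
        e_o1 = (added[channel_index("O1")] ** 2).sum()
        assert e_fp1 > 0
        assert e_o1 < 0.3 * e_fp1

    def test_negative_rate_rejected(self):
        rec = make_background(30, 200, seed=1)
        with pytest.raises(ValueError):
            inject_eye_blinks(rec, -1.0)


class TestCohort:
    def test_counts_and_label_purity(self, tiny_cohort):
        assert len(tiny_cohort) == 10
        annotated = [s for s in tiny_cohort if len(s.annotations)]
        assert len(annotated) == 6
        controls = [s for s in tiny_cohort if s.metadata["group"] == "control"]
        assert len(controls) == 4
        for s in controls:
            assert len(s.annotations) == 0
        for s in annotated:
            assert s.annotations.regions() == {s.metadata["region"]}

    def test_reproducible_from_seed(self):
        cfg = scaled_cohort_config(n_frontal=1, n_temporal=0, n_occipital=1,
                                   n_controls=1)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.recording.signal, sb.recording.signal)
            assert [e.onset_s for e in sa.annotations] == [
                e.onset_s for e in sb.annotations
            ]

    def test_events_centerable_in_full_epochs(self, tiny_cohort):
        for s in tiny_cohort:
            T = s.recording.duration_s
            for ev in s.annotations:
                assert 0.75 <= ev.center_s <= T - 0.75

    def test_occipital_count_calibration(self):
        """Grand-mean occipital IED count stays within 3 SE of the configured
        mean of 127 over a Monte-Carlo of cohort-scale draws."""
        mean = 127.0
        draws = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            draws += [draw_ied_count(rng, mean) for _ in range(10)]
        draws = np.asarray(draws, float)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se + 1e-9

    def test_duration_sampler_stays_in_envelope(self, rng):
        sampler = default_duration_sampler(0.48, 0.1)
        for _ in range(200):
            spike, wave = sampler(rng)
            assert 0.2 <= spike + wave <= 1.2
            assert 0.02 <= spike <= 0.2


class TestConfigValidation:
    def test_rejects_short_recordings(self):
        with pytest.raises(ValueError):
            scaled_cohort_config(recording_duration_s=5.0)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            scaled_cohort_config(n_controls=-1)

    def test_rejects_out_of_envelope_durations(self):
        with pytest.raises(ValueError):
            scaled_cohort_config(
                ied_duration_mean_s={"frontal": 5.0, "temporal": 0.5, "occipital": 0.5}
            )
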