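"""Synthetic-trial generator: templates, recordings, interventions, trials."""

import numpy as np
import pytest

from ecgtf.errors import ParameterError
from ecgtf.sysid import DiscreteTransferFunction, goodness_of_fit, simulate_tf
from ecgtf.synthetic import (
    DEFAULT_WAVE_PARAMS,
    TrialConfig,
    apply_intervention,
    default_ground_truth_tfs,
    generate_trial,
    make_beat_template,
    noise_free_config,
    synthesize_recording,
    tf_from_early_response,
)


class TestBeatTemplate:
    def test_zero_amplitudes_render_zeros(self):
        params = tuple((0.0, c, w) for _, c, w in DEFAULT_WAVE_PARAMS)
        tpl = make_beat_template(params, duration=0.8, fs=256.0)
        assert np.all(tpl.samples == 0.0)

    def test_single_r_bump_peaks_at_its_center(self):
        params = ((0.0, -0.1, 0.02), (0.0, -0.05, 0.02), (1.0, 0.0, 0.010),
                  (0.0, 0.05, 0.02), (0.0, 0.2, 0.02))
        tpl = make_beat_template(params, duration=0.8, fs=256.0)
        assert int(np.argmax(tpl.samples)) == tpl.r_index

    def test_default_template_length_and_peak_value(self):
        tpl = make_beat_template(fs=256.0, duration=0.8)
        assert len(tpl) == round(0.8 * 256)
        # oracle: evaluate the five-Gaussian sum directly at the R center time
        t_r = tpl.r_index / 256.0
        expected = sum(
            a * np.exp(-((t_r - (0.35 * 0.8 + c)) ** 2) / (2 * w**2))
            for a, c, w in DEFAULT_WAVE_PARAMS
        )
        assert np.max(tpl.samples) == pytest.approx(expected, abs=1e-6)

    def test_nonpositive_width_rejected(self):
        bad = ((1.0, 0.0, 0.0),) + DEFAULT_WAVE_PARAMS[1:]
        with pytest.raises(ParameterError):
            make_beat_template(bad)


class TestSynthesizeRecording:
    def test_deterministic_limit_is_exactly_periodic(self):
        tpl = make_beat_template(fs=256.0)
        rec = synthesize_recording(
            tpl, duration=10.0, mean_hr=60.0, rr_jitter_sd=0.0,
            noise_sd=0.0, baseline_wander_amp=0.0, artifact_rate=0.0, seed=0,
        )
        assert len(rec.true_r_indices) == 10
        assert np.all(np.diff(rec.true_r_indices) == 256)
        # all beats identical
        first = rec.samples[0:256]
        for r in rec.true_r_indices[1:-1]:
            start = r - tpl.r_index
            np.testing.assert_array_equal(rec.samples[start : start + 256], first)

    def test_same_seed_is_bit_identical(self):
        tpl = make_beat_template(fs=256.0)
        kwargs = dict(duration=20.0, mean_hr=70.0, rr_jitter_sd=0.02,
                      noise_sd=0.05, baseline_wander_amp=0.1, artifact_rate=0.1)
        a = synthesize_recording(tpl, seed=7, **kwargs)
        b = synthesize_recording(tpl, seed=7, **kwargs)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.true_r_indices, b.true_r_indices)
        assert a.artifact_beat_indices == b.artifact_beat_indices

    def test_beat_count_tracks_heart_rate(self):
        tpl = make_beat_template(fs=256.0)
        rec = synthesize_recording(
            tpl, duration=300.0, mean_hr=70.0, rr_jitter_sd=0.02,
            noise_sd=0.0, baseline_wander_amp=0.0, artifact_rate=0.0, seed=7,
        )
        assert abs(len(rec.true_r_indices) - round(300 * 70 / 60)) <= 2

    def test_artifact_beats_are_three_times_larger(self):
        tpl = make_beat_template(fs=256.0)
        rec = synthesize_recording(
            tpl, duration=60.0, mean_hr=60.0, rr_jitter_sd=0.0,
            noise_sd=0.0, baseline_wander_amp=0.0, artifact_rate=0.2, seed=3,
        )
        assert rec.artifact_beat_indices
        clean_max = np.max(np.abs(tpl.samples))
        for k in rec.artifact_beat_indices:
            r = rec.true_r_indices[k]
            start = r - tpl.r_index
            window = rec.samples[start : start + len(tpl)]
            assert np.max(np.abs(window)) == pytest.approx(3 * clean_max)

    def test_too_short_duration_rejected(self):
        tpl = make_beat_template(fs=256.0)
        with pytest.raises(ParameterError):
            synthesize_recording(tpl, duration=1.0, mean_hr=60.0,
                                 rr_jitter_sd=0, noise_sd=0,
                                 baseline_wander_amp=0, artifact_rate=0, seed=0)


class TestApplyIntervention:
    def test_unit_delay_shifts_template(self):
        tpl = make_beat_template(fs=256.0)
        tf = DiscreteTransferFunction(num=(1.0,), den=(1.0, 0.0))
        out = apply_intervention(tpl.samples, tf)
        assert out[0] == 0.0
        np.testing.assert_allclose(out[1:], tpl.samples[:-1])

    def test_half_gain_delay(self):
        tpl = make_beat_template(fs=256.0)
        tf = DiscreteTransferFunction(num=(0.5,), den=(1.0, 0.0))
        out = apply_intervention(tpl.samples, tf)
        np.testing.assert_allclose(out[1:], 0.5 * tpl.samples[:-1])

    def test_impulse_hand_recursion(self):
        tf = DiscreteTransferFunction(num=(1.0,), den=(1.0, -0.5))
        impulse = np.zeros(6)
        impulse[0] = 1.0
        out = apply_intervention(impulse, tf)
        np.testing.assert_allclose(out, [0, 1, 0.5, 0.25, 0.125, 0.0625])

    def test_ground_truth_tfs_preserve_r_argmax(self):
        """R-alignment must not cancel the modelled intervention (see docs)."""
        tpl = make_beat_template(fs=256.0)
        for tf in default_ground_truth_tfs().values():
            out = apply_intervention(tpl.samples, tf)
            assert int(np.argmax(out)) == tpl.r_index


class TestGenerateTrial:
    def test_noise_free_during_template_is_simulated_before(self, clean_trial):
        g = clean_trial.subject_tfs[("sub01", "BDA")]
        before = clean_trial.recordings[("sub01", "before")]
        during = clean_trial.recordings[("sub01", "during")]
        np.testing.assert_array_equal(
            during.template_samples, simulate_tf(g, before.template_samples)
        )

    def test_full_trial_size_and_determinism(self):
        cfg = TrialConfig(n_subjects=14, period_duration=10.0, seed=9)
        a = generate_trial(cfg)
        b = generate_trial(cfg)
        assert len(a.recordings) == 42
        for key in a.recordings:
            np.testing.assert_array_equal(
                a.recordings[key].samples, b.recordings[key].samples
            )

    def test_adding_subjects_never_reshuffles_earlier_ones(self):
        small = generate_trial(TrialConfig(n_subjects=2, period_duration=10.0, seed=4))
        large = generate_trial(TrialConfig(n_subjects=4, period_duration=10.0, seed=4))
        for key, rec in small.recordings.items():
            np.testing.assert_array_equal(rec.samples, large.recordings[key].samples)

    def test_homogeneous_subjects_have_identical_ground_truth(self):
        trial = generate_trial(
            noise_free_config(n_subjects=3, period_duration=10.0, seed=2)
        )
        tfs = [trial.subject_tfs[(s, "BDA")] for s in trial.subject_ids]
        assert all(t.num == tfs[0].num and t.den == tfs[0].den for t in tfs)

    def test_homogeneous_itfs_agree_across_subjects(self, order23_tfs):
        """With no subject variation, downstream ITF estimates coincide."""
        from ecgtf import SampledSignal, build_saecg, estimate_tf
        from ecgtf.generalize import pair_saecgs

        cfg = noise_free_config(
            n_subjects=3, period_duration=20.0, seed=6,
            ground_truth_tf_by_pair=order23_tfs,
        )
        trial = generate_trial(cfg)
        fits = []
        for sid in trial.subject_ids:
            sa_b = build_saecg(
                SampledSignal(trial.recordings[(sid, "before")].samples, 256.0)
            )
            sa_d = build_saecg(
                SampledSignal(trial.recordings[(sid, "during")].samples, 256.0)
            )
            fits.append(estimate_tf(*pair_saecgs(sa_b, sa_d), 2, 3))
        ref = np.concatenate([fits[0].tf.num, fits[0].tf.den])
        for f in fits[1:]:
            vec = np.concatenate([f.tf.num, f.tf.den])
            np.testing.assert_allclose(vec, ref, atol=1e-3)


def test_tf_from_early_response_prescribes_the_early_taps():
    early = [1.2, -0.6, 0.3]
    tf = tf_from_early_response(early, poles=[0.4, -0.3, 0.2], dc_gain=1.0)
    impulse = np.zeros(16)
    impulse[0] = 1.0
    h = simulate_tf(tf, impulse)
    # prescribed up to the DC-gain rescaling: shape of lags 1..3 preserved
    np.testing.assert_allclose(h[1:4] / h[1], np.array(early) / early[0], atol=1e-12)
    # and DC gain is 1
    assert np.sum(simulate_tf(tf, np.ones(4000))[-1]) == pytest.approx(1.0, abs=1e-6)
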