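"""Band-pass filtering, QRS detection, segmentation, rejection, SAECG averaging."""

import numpy as np
import pytest

from ecgtf.errors import DegenerateDataError, InsufficientDataError, ParameterError
from ecgtf.preprocess import (
    Beat,
    RPeakList,
    SampledSignal,
    bandpass_filter,
    build_saecg,
    detect_r_peaks,
    reject_abnormal_beats,
    segment_beats,
)
from ecgtf.synthetic import make_beat_template, noise_free_config, synthesize_recording

from conftest import recording_signal


def _sine(freq, fs=256.0, duration=60.0):
    t = np.arange(int(duration * fs)) / fs
    return SampledSignal(samples=np.sin(2 * np.pi * freq * t), fs=fs)


class TestBandpass:
    def test_dc_is_removed(self):
        sig = SampledSignal(samples=np.ones(2560), fs=256.0)
        out = bandpass_filter(sig)
        assert np.mean(np.abs(out.samples)) < 1e-3

    def test_passband_preserves_10hz(self):
        out = bandpass_filter(_sine(10.0))
        ratio = np.std(out.samples) / np.std(_sine(10.0).samples)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuates_slow_drift(self):
        out = bandpass_filter(_sine(0.05))
        assert np.std(out.samples) < 0.1 * np.std(_sine(0.05).samples)

    def test_output_length_preserved(self):
        out = bandpass_filter(_sine(5.0, duration=3.0))
        assert len(out) == len(_sine(5.0, duration=3.0))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            bandpass_filter(_sine(10.0), high_hz=200.0)


class TestDetectRPeaks:
    def test_flat_signal_yields_no_peaks(self):
        sig = SampledSignal(samples=np.zeros(1024), fs=256.0)
        assert len(detect_r_peaks(sig)) == 0

    def test_single_beat_found_at_template_r(self):
        tpl = make_beat_template(fs=256.0)
        padded = np.zeros(512)
        padded[100 : 100 + len(tpl)] = tpl.samples
        peaks = detect_r_peaks(SampledSignal(samples=padded, fs=256.0))
        assert len(peaks) == 1
        assert abs(peaks.indices[0] - (100 + tpl.r_index)) <= 1

    def test_all_true_beats_matched_no_extras(self):
        tpl = make_beat_template(fs=256.0)
        rec = synthesize_recording(
            tpl, duration=30.0, mean_hr=60.0, rr_jitter_sd=0.02,
            noise_sd=0.01, baseline_wander_amp=0.05, artifact_rate=0.0, seed=2,
        )
        filt = bandpass_filter(SampledSignal(samples=rec.samples, fs=256.0))
        peaks = detect_r_peaks(filt).indices
        tol = round(0.010 * 256)
        assert len(peaks) == len(rec.true_r_indices)
        assert np.all(np.abs(peaks - rec.true_r_indices) <= tol)

    def test_sensitivity_and_precision_on_noisy_recordings(self):
        """>= 99% of true R peaks found, >= 99% of detections true."""
        tpl = make_beat_template(fs=256.0)
        tp = fp = fn = 0
        for seed in range(4):
            rec = synthesize_recording(
                tpl, duration=60.0, mean_hr=70.0, rr_jitter_sd=0.03,
                noise_sd=0.1, baseline_wander_amp=0.1, artifact_rate=0.02,
                seed=seed,
            )
            filt = bandpass_filter(SampledSignal(samples=rec.samples, fs=256.0))
            peaks = list(detect_r_peaks(filt).indices)
            tol = round(0.020 * 256)
            used = set()
            for t in rec.true_r_indices:
                hit = [p for p in peaks if abs(p - t) <= tol and p not in used]
                if hit:
                    tp += 1
                    used.add(hit[0])
                else:
                    fn += 1
            fp += len(peaks) - len(used)
        assert tp / (tp + fn) >= 0.99
        assert tp / (tp + fp) >= 0.99

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            detect_r_peaks(SampledSignal(samples=np.zeros(256), fs=256.0))


class TestSegmentBeats:
    def test_regular_peaks_forced_arithmetic(self):
        fs = 256.0
        peaks = RPeakList(indices=np.arange(10) * 256 + 300)
        sig = SampledSignal(samples=np.random.default_rng(0).normal(size=3500), fs=fs)
        beats = segment_beats(sig, peaks)
        assert all(len(b.samples) == 256 for b in beats)
        assert all(b.r_offset == 89 for b in beats)  # floor(0.35 * 256)

    def test_window_underflow_drops_first_beat(self):
        peaks = RPeakList(indices=np.array([10, 266, 522, 778]))
        sig = SampledSignal(samples=np.zeros(1200), fs=256.0)
        beats = segment_beats(sig, peaks)
        assert len(beats) == 3  # the beat at sample 10 underflows

    def test_beat_length_recomputed_from_realized_rr(self):
        rng = np.random.default_rng(3)
        rr = (0.8 + rng.normal(0, 0.02, 20)) * 256
        idx = (200 + np.cumsum(rr)).astype(int)
        sig = SampledSignal(samples=np.zeros(int(idx[-1] + 500)), fs=256.0)
        beats = segment_beats(sig, RPeakList(indices=idx))
        expected_len = round(256 * np.mean(np.diff(idx)) / 256)
        assert len(beats[0].samples) == expected_len

    def test_fewer_than_two_peaks_rejected(self):
        sig = SampledSignal(samples=np.zeros(1024), fs=256.0)
        with pytest.raises(InsufficientDataError):
            segment_beats(sig, RPeakList(indices=np.array([500])))


def _beat(samples):
    return Beat(samples=np.asarray(samples, dtype=float), r_offset=0, fs=256.0)


class TestRejectAbnormalBeats:
    def test_identical_beats_all_kept(self):
        beats = [_beat([0.1, 1.0, 0.2])] * 8
        kept, n = reject_abnormal_beats(beats)
        assert len(kept) == 8 and n == 0

    def test_triple_amplitude_beat_rejected(self):
        # mean-beat max = (9*1 + 3)/10 = 1.2, threshold 2.4: only the x3 beat fails
        beats = [_beat([0.0, 1.0, 0.0])] * 9 + [_beat([0.0, 3.0, 0.0])]
        kept, n = reject_abnormal_beats(beats)
        assert n == 1 and len(kept) == 9
        assert all(b.samples[1] == 1.0 for b in kept)

    def test_one_and_a_half_amplitude_beat_kept(self):
        # mean-beat max = 1.05, threshold 2.1 > 1.5: nothing rejected
        beats = [_beat([0.0, 1.0, 0.0])] * 9 + [_beat([0.0, 1.5, 0.0])]
        kept, n = reject_abnormal_beats(beats)
        assert n == 0 and len(kept) == 10

    def test_rule_is_scale_equivariant(self):
        rng = np.random.default_rng(1)
        shape = np.sin(np.arange(16) / 3.0)
        base = [_beat(shape * g) for g in rng.uniform(0.9, 1.1, 12)]
        base.append(_beat(10.0 * shape))
        kept1, n1 = reject_abnormal_beats(base)
        scaled = [_beat(37.0 * b.samples) for b in base]
        kept2, n2 = reject_abnormal_beats(scaled)
        assert n1 == n2 == 1
        np.testing.assert_array_equal(
            [np.max(np.abs(b.samples)) for b in kept2],
            [37.0 * np.max(np.abs(b.samples)) for b in kept1],
        )

    def test_all_rejected_is_degenerate(self):
        # a single pathological configuration cannot leave zero beats under
        # the x2-of-mean rule with one beat, so use the explicit error path
        with pytest.raises(ParameterError):
            reject_abnormal_beats([])


class TestBuildSaecg:
    def test_noise_free_saecg_close_to_rendered_beat(self, clean_trial):
        sig = recording_signal(clean_trial, "sub01", "before")
        rec = clean_trial.recordings[("sub01", "before")]
        sa = build_saecg(sig)
        # compare on the overlap around R; band-pass edge effects allowed
        tpl = rec.template_samples
        pre = min(sa.r_offset, rec.template_r_index)
        post = min(len(sa) - sa.r_offset, len(tpl) - rec.template_r_index)
        a = sa.samples[sa.r_offset - pre : sa.r_offset + post]
        b = tpl[rec.template_r_index - pre : rec.template_r_index + post]
        nrmse = np.linalg.norm(a - b) / np.linalg.norm(b)
        assert nrmse < 0.05

    def test_averaging_beats_down_noise(self):
        """SAECG noise shrinks as 1/sqrt(beats averaged)."""
        noise_sd = 0.05
        tpl = make_beat_template(fs=256.0)
        common = dict(duration=300.0, mean_hr=60.0, rr_jitter_sd=0.0,
                      baseline_wander_amp=0.0, artifact_rate=0.0, seed=12)
        clean = synthesize_recording(tpl, noise_sd=0.0, **common)
        noisy = synthesize_recording(tpl, noise_sd=noise_sd, **common)
        sa_clean = build_saecg(SampledSignal(samples=clean.samples, fs=256.0))
        sa_noisy = build_saecg(SampledSignal(samples=noisy.samples, fs=256.0))
        assert sa_noisy.n_used >= 290
        rms = np.sqrt(np.mean((sa_noisy.samples - sa_clean.samples) ** 2))
        assert rms < noise_sd / np.sqrt(200)

    def test_injected_artifacts_are_rejected(self):
        tpl = make_beat_template(fs=256.0)
        rec = synthesize_recording(
            tpl, duration=60.0, mean_hr=60.0, rr_jitter_sd=0.0,
            noise_sd=0.01, baseline_wander_amp=0.0, artifact_rate=0.05, seed=8,
        )
        n_interior = sum(
            1 for k in rec.artifact_beat_indices
            if 0 < k < len(rec.true_r_indices) - 1
        )
        sa = build_saecg(SampledSignal(samples=rec.samples, fs=256.0))
        assert rec.artifact_beat_indices  # the draw did inject artifacts
        assert sa.n_rejected == n_interior

    def test_prepended_baseline_leaves_saecg_unchanged(self, clean_trial):
        sig = recording_signal(clean_trial, "sub01", "before")
        sa = build_saecg(sig)
        padded = SampledSignal(
            samples=np.concatenate([np.zeros(2 * len(sa)), sig.samples]), fs=sig.fs
        )
        sa_padded = build_saecg(padded)
        assert len(sa_padded) == len(sa)
        assert np.max(np.abs(sa_padded.samples - sa.samples)) < 1e-2
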