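"""Tests of epoching, artifact rejection, averaging, and rule-based P50
scoring, including exact equivalence with an exhaustive-scan reference."""

import numpy as np
import pandas as pd
import pytest

from gatebeat.gating import (
    GatingResult,
    UnusableSubjectError,
    average_epochs,
    detect_p50_s1,
    detect_p50_s2,
    epoch_and_baseline,
    gating_ratio,
    reject_epochs,
    score_gating,
)
from gatebeat.records import EEGRecording


def _mini_recording(n_ch=2, fs=512.0, duration=30.0, value=0.0):
    data = np.full((n_ch, int(duration * fs)), value)
    return EEGRecording(data, fs, [f"ch{i}" for i in range(n_ch)])


def _markers(times, label="S1"):
    return pd.DataFrame({"onset_s": times, "label": [label] * len(times)})


# ---------------------------------------------------------------------------
# exhaustive-scan reference for the P50 rules (independent of the package's
# vectorized implementation: plain per-sample loops, applied literally)
# ---------------------------------------------------------------------------

def p50_reference(w, t, lo=40.0, hi=80.0):
    best = None
    for i in range(1, len(w) - 1):
        if not (lo <= t[i] <= hi):
            continue
        if not (w[i] > w[i - 1] and w[i] > w[i + 1]):
            continue
        if best is None or w[i] > w[best]:
            best = i
    if best is None:
        return None
    trough = None
    for j in range(1, best):
        if t[j] >= 0 and w[j] < w[j - 1] and w[j] < w[j + 1]:
            trough = j
    if trough is not None:
        tv = w[trough]
    else:
        pre = [w[j] for j in range(best) if t[j] >= 0]
        tv = min(pre) if pre else w[best]
    return (w[best] - tv, t[best])


class TestEpochAndBaseline:
    def test_constant_offset_removed(self):
        rec = _mini_recording(value=3.0)
        es = epoch_and_baseline(rec, _markers([5.0, 15.0]), "S1")
        assert np.allclose(es.epochs, 0.0)
        assert es.n_trials == 2
        assert es.times_ms[0] >= -100.0 and es.times_ms[-1] <= 400.0

    def test_step_at_stimulus_onset(self):
        rec = _mini_recording()
        data = rec.data.copy()
        onset = int(10.0 * rec.fs)
        data[:, onset:] = 2.0
        rec = EEGRecording(data, rec.fs, rec.ch_names)
        es = epoch_and_baseline(rec, _markers([10.0]), "S1")
        pre = es.epochs[0, :, es.times_ms < 0]
        post = es.epochs[0, :, es.times_ms >= 0]
        assert np.allclose(pre, 0.0)
        assert np.allclose(post, 2.0)

    def test_edge_markers_skipped(self):
        rec = _mini_recording(duration=10.0)
        es = epoch_and_baseline(rec, _markers([0.1, 5.0, 9.95]), "S1")
        assert es.n_trials == 1

    def test_full_session_epoch_counts(self, clean_session):
        rec, markers = clean_session
        for cond in ("S1", "S2"):
            es = epoch_and_baseline(rec, markers, cond)
            assert es.n_trials == 20


class TestRejectEpochs:
    def _epochs_with_peaks(self, peaks):
        rec = _mini_recording(duration=60.0)
        data = rec.data.copy()
        times = 5.0 + 2.0 * np.arange(len(peaks))
        for t0, pk in zip(times, peaks):
            data[0, int((t0 + 0.1) * rec.fs)] = pk
        rec = EEGRecording(data, rec.fs, rec.ch_names)
        return reject_epochs(epoch_and_baseline(rec, _markers(times), "S1"))

    def test_exceeding_trial_dropped_boundary_retained(self):
        es = self._epochs_with_peaks([80.0, 74.0, 75.0, -80.0])
        assert list(es.retained_mask) == [False, True, True, False]

    def test_all_within_threshold_none_dropped(self):
        es = self._epochs_with_peaks([10.0, -20.0, 74.0])
        assert es.retained_mask.all()

    def test_all_rejected_raises(self):
        with pytest.raises(ValueError, match="every trial"):
            self._epochs_with_peaks([200.0, 300.0])

    def test_rejection_matches_amplitude_rule(self, noisy_session):
        rec, markers = noisy_session
        es = epoch_and_baseline(rec, markers, "S1")
        out = reject_epochs(es)
        peaks = np.abs(es.epochs).max(axis=(1, 2))
        assert np.array_equal(out.retained_mask, peaks <= 75.0)
        assert (peaks[~out.retained_mask] > 75.0).all()


class TestAverageEpochs:
    def test_identical_and_symmetric_trials(self):
        rec = _mini_recording()
        es = epoch_and_baseline(rec, _markers([5.0, 15.0]), "S1")
        es.epochs[0] += 4.0
        es.epochs[1] += 4.0
        assert np.allclose(average_epochs(es), 4.0)
        es.epochs[1] = -es.epochs[0]
        assert np.allclose(average_epochs(es), 0.0)

    def test_noise_shrinks_with_trial_count(self, rng):
        signal = np.sin(np.linspace(0, 4 * np.pi, 256))
        rms = {}
        for n in (4, 64):
            trials = signal + rng.standard_normal((n, 256))
            rms[n] = np.sqrt(np.mean((trials.mean(axis=0) - signal) ** 2))
        assert rms[64] < rms[4] / 2  # expect ~1/4 at 16x the trials

    def test_zero_retained_raises(self):
        rec = _mini_recording()
        es = epoch_and_baseline(rec, _markers([5.0]), "S1")
        es.retained_mask[:] = False
        with pytest.raises(ValueError):
            average_epochs(es)


class TestDetectP50:
    def _grid(self):
        return np.arange(-100, 401, 2).astype(float)  # 2 ms steps

    def test_constructed_peak_and_trough(self):
        t = self._grid()
        w = np.zeros_like(t)
        w[t == 60.0] = 5.0
        w[t == 34.0] = -2.0
        res = detect_p50_s1(w, t)
        assert res.latency == 60.0
        assert res.amplitude == pytest.approx(7.0)

    def test_monotone_ramp_has_no_peak(self):
        t = self._grid()
        res = detect_p50_s1(t * 0.01, t)
        assert res is None

    def test_largest_peak_wins_earliest_on_tie(self):
        t = self._grid()
        w = np.zeros_like(t)
        w[t == 50.0] = 3.0
        w[t == 70.0] = 3.0
        res = detect_p50_s1(w, t)
        assert res.latency == 50.0

    def test_matches_exhaustive_reference_on_random_waveforms(self, rng):
        t = np.arange(-100, 401, 1000.0 / 512.0)
        for _ in range(300):
            w = rng.standard_normal(t.size).cumsum()  # smooth-ish random walk
            w -= w[t < 0].mean()
            ours = detect_p50_s1(w, t)
            ref = p50_reference(w, t)
            if ref is None:
                assert ours is None
            else:
                assert ours.amplitude == ref[0]
                assert ours.latency == ref[1]

    def test_s2_peak_within_latency_window_accepted(self):
        t = self._grid()
        w = np.zeros_like(t)
        w[t == 58.0] = 4.0
        amp, lat, att = detect_p50_s2(w, t, s1_lat=50.0)
        assert (amp, lat, att) == (pytest.approx(4.0), 58.0, False)

    def test_s2_peak_outside_window_is_attenuated(self):
        t = self._grid()
        w = np.zeros_like(t)
        w[t == 66.0] = 4.0  # 16 ms after S1 peak: outside +/-10 ms
        amp, lat, att = detect_p50_s2(w, t, s1_lat=50.0)
        assert (amp, lat, att) == (0.0, 50.0, True)

    def test_s2_flat_average_is_attenuated(self):
        t = self._grid()
        amp, lat, att = detect_p50_s2(np.zeros_like(t), t, s1_lat=55.0)
        assert (amp, lat, att) == (0.0, 55.0, True)


class TestGatingRatio:
    @pytest.mark.parametrize("s1,s2,expected", [(5.0, 0.0, 0.0), (5.0, 5.0, 1.0),
                                                (4.0, 2.0, 0.5), (4.0, 6.0, 1.5)])
    def test_ratio_values(self, s1, s2, expected):
        assert gating_ratio(s1, s2) == pytest.approx(expected)

    def test_unusable_without_s1(self):
        with pytest.raises(UnusableSubjectError):
            gating_ratio(0.0, 1.0)


class TestEndToEnd:
    def test_noise_free_ratio_recovered_exactly(self, clean_session):
        rec, markers = clean_session
        res = score_gating(rec, markers)
        assert res.ratio == pytest.approx(0.5, abs=1e-6)
        assert res.n_retained_s1 == res.n_retained_s2 == 20
        assert 40.0 <= res.s1_lat <= 80.0

    def test_fully_suppressed_s2(self):
        from gatebeat.synth import GatingSimParams, synth_eeg_session

        rec, markers = synth_eeg_session(
            GatingSimParams(n_pairs=10, true_ratio=0.0, background_rms=0.0,
                            artifact_rate=0.0, seed=17)
        )
        res = score_gating(rec, markers)
        assert res.s2_amp == 0.0
        assert res.attenuated_s2
        assert res.s2_lat == res.s1_lat

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            GatingResult(s1_amp=5.0, s2_amp=1.0, s1_lat=30.0, s2_lat=30.0,
                         ratio=0.2, n_retained_s1=1, n_retained_s2=1,
                         attenuated_s2=False)
        with pytest.raises(ValueError):
            GatingResult(s1_amp=5.0, s2_amp=1.0, s1_lat=50.0, s2_lat=70.0,
                         ratio=0.2, n_retained_s1=1, n_retained_s2=1,
                         attenuated_s2=False)
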