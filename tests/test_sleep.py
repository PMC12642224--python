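"""Sleep staging, REM architecture, spindle and spike detection."""

import numpy as np
import pandas as pd
import pytest

from copath.simulate import PlantedEEGSpec, simulate_eeg
from copath.sleep import (
    Hypnogram,
    Recording,
    StagingThresholds,
    detect_spikes,
    detect_spindles,
    epoch_features,
    rem_metrics,
    spindle_summary,
    stage_sleep,
)


def make_recording(eeg, fs=200.0, emg=None, movement=None):
    n = len(eeg)
    return Recording(eeg=np.asarray(eeg, dtype=float),
                     emg=np.zeros(n) if emg is None else emg,
                     movement=np.zeros(n) if movement is None else movement,
                     sampling_rate=fs)


class TestEpochFeatures:
    def test_pure_delta_sine_dominates(self):
        fs, t = 200.0, np.arange(0, 20, 1 / 200.0)
        rec = make_recording(50 * np.sin(2 * np.pi * 2.0 * t), fs)
        f = epoch_features(rec, epoch_len=10.0)
        assert (f["delta_power"] > 10 * f["theta_power"]).all()

    def test_pure_theta_sine_dominates(self):
        fs, t = 200.0, np.arange(0, 20, 1 / 200.0)
        rec = make_recording(50 * np.sin(2 * np.pi * 7.0 * t), fs)
        f = epoch_features(rec, epoch_len=10.0)
        assert (f["theta_power"] > 10 * f["delta_power"]).all()

    def test_zero_signal_gives_zero_features(self):
        rec = make_recording(np.zeros(4000))
        f = epoch_features(rec, epoch_len=10.0)
        assert np.allclose(f.to_numpy(), 0.0)

    def test_epoch_longer_than_recording_rejected(self):
        rec = make_recording(np.zeros(100))
        with pytest.raises(ValueError, match="longer"):
            epoch_features(rec, epoch_len=10.0)


class TestStaging:
    def _features(self, rows):
        return pd.DataFrame(
            rows, columns=["delta_power", "theta_power", "emg_rms",
                           "movement_mean"])

    def test_high_emg_throughout_is_all_wake(self):
        f = self._features([[1.0, 1.0, 50.0, 5.0]] * 6)
        thr = StagingThresholds(emg=10.0, movement=1.0,
                                theta_delta_ratio=2.0, delta=5.0)
        h = stage_sleep(f, thr)
        assert h.states == ["Wake"] * 6

    def test_rem_signature_after_wake_scored_qw(self):
        # epoch 1 has a REM signature (high theta/delta, silent EMG) but
        # follows Wake, so the no-Wake->REM rule forces QW
        f = self._features([
            [1.0, 1.0, 50.0, 5.0],   # Wake
            [1.0, 10.0, 0.1, 0.0],   # REM-like, after Wake -> QW
            [9.0, 1.0, 0.1, 0.0],    # NREM
            [1.0, 10.0, 0.1, 0.0],   # REM (follows NREM)
        ])
        thr = StagingThresholds(emg=10.0, movement=1.0,
                                theta_delta_ratio=2.0, delta=5.0)
        h = stage_sleep(f, thr)
        assert h.states == ["Wake", "QW", "NREM", "REM"]

    def test_identical_features_warn_single_state(self):
        f = self._features([[1.0, 1.0, 1.0, 1.0]] * 5)
        with pytest.warns(UserWarning, match="identical"):
            h = stage_sleep(f)
        assert len(set(h.states)) == 1

    def test_planted_hypnogram_recovered(self):
        """Auto-thresholded staging agrees with the planted hypnogram on
        >= 90% of epochs at the generator's default SNR."""
        sim = simulate_eeg(PlantedEEGSpec(sampling_rate=200.0,
                                          spike_rate=0.0), seed=6)
        feats = epoch_features(sim.recording)
        h = stage_sleep(feats)
        agree = np.mean([a == b for a, b in
                         zip(h.states, sim.hypnogram.states)])
        assert agree >= 0.9

    def test_state_counts_partition_epochs(self):
        sim = simulate_eeg(PlantedEEGSpec(sampling_rate=200.0,
                                          spike_rate=0.0), seed=6)
        h = stage_sleep(epoch_features(sim.recording))
        counts = pd.Series(h.states).value_counts()
        assert counts.sum() == len(h)


class TestRemMetrics:
    def test_no_rem_gives_zeros(self):
        h = Hypnogram(states=["Wake", "NREM", "QW", "NREM"])
        m = rem_metrics(h).loc["all"]
        assert m["rem_percent_time"] == 0.0
        assert m["rem_percent_bouts"] == 0.0
        assert m["nrem_rem_transitions"] == 0

    def test_hand_enumerated_bouts_and_transitions(self):
        h = Hypnogram(states=["NREM", "REM", "REM", "NREM", "REM"])
        m = rem_metrics(h).loc["all"]
        assert m["rem_bouts"] == 2
        assert m["nrem_rem_transitions"] == 2
        assert m["rem_percent_time"] == pytest.approx(60.0)

    def test_phase_split_partitions_counts(self):
        states = ["Wake", "NREM", "REM", "NREM", "REM", "Wake", "QW", "NREM"]
        phases = ["light"] * 4 + ["dark"] * 4
        h = Hypnogram(states=states)
        m = rem_metrics(h, phase_labels=phases)
        for col in ("nrem_rem_transitions", "rem_bouts", "total_bouts",
                    "n_epochs"):
            assert m.loc["light", col] + m.loc["dark", col] == m.loc["all", col]


class TestSpindles:
    def test_single_planted_spindle_recovered(self):
        """A clearly visible 1 s, 12 Hz spindle is recovered as one event
        with frequency within 0.5 Hz and duration within 0.2 s."""
        spec = PlantedEEGSpec(
            sampling_rate=500.0,
            state_sequence=[("Wake", 100.0), ("NREM", 120.0), ("QW", 100.0)],
            spindle_rate=0.5, spindle_duration_range=(1.0, 1.0),
            spindle_snr=6.0, spike_rate=0.0)
        sim = simulate_eeg(spec, seed=3)
        assert len(sim.spindles) == 1
        truth = sim.spindles[0]
        events = detect_spindles(sim.recording, sim.hypnogram)
        hits = [e for e in events
                if e.onset < truth.onset + truth.duration
                and e.onset + e.duration > truth.onset]
        assert len(hits) == 1
        assert hits[0].oscillation_frequency == pytest.approx(12.0, abs=0.5)
        assert hits[0].duration == pytest.approx(truth.duration, abs=0.2)

    def test_silent_recording_yields_no_events(self):
        rec = make_recording(np.zeros(30 * 200), fs=200.0)
        h = Hypnogram(states=["NREM"] * 3)
        assert detect_spindles(rec, h) == []

    def test_no_nrem_warns_and_returns_empty(self):
        rec = make_recording(np.random.default_rng(0).normal(size=6000))
        h = Hypnogram(states=["Wake"] * 3)
        with pytest.warns(UserWarning, match="no NREM"):
            assert detect_spindles(rec, h) == []

    def test_detected_events_lie_within_nrem(self):
        sim = simulate_eeg(PlantedEEGSpec(spike_rate=0.0), seed=4)
        events = detect_spindles(sim.recording, sim.hypnogram)
        nrem = sim.hypnogram.state_mask("NREM", 500.0,
                                        sim.recording.eeg.size)
        for e in events:
            a = int(e.onset * 500)
            b = int((e.onset + e.duration) * 500)
            assert nrem[a:b].all()

    def test_bad_band_rejected(self):
        rec = make_recording(np.zeros(4000))
        h = Hypnogram(states=["NREM"] * 2)
        with pytest.raises(ValueError, match="Nyquist"):
            detect_spindles(rec, h, band=(10.0, 150.0))


class TestSpindleSummary:
    def _events(self, n):
        from copath.sleep import SpindleEvent

        return [SpindleEvent(onset=i * 10.0, duration=1.0,
                             peak_amplitude=40.0, oscillation_frequency=12.0)
                for i in range(n)]

    def test_abundance_per_nrem_minute(self):
        h = Hypnogram(states=["NREM"] * 30)  # 300 s = 5 min
        s = spindle_summary(self._events(10), h)
        assert s["abundance_per_min"] == pytest.approx(2.0)

    def test_abundance_halves_when_nrem_doubles(self):
        h1 = Hypnogram(states=["NREM"] * 30)
        h2 = Hypnogram(states=["NREM"] * 60)
        a1 = spindle_summary(self._events(10), h1)["abundance_per_min"]
        a2 = spindle_summary(self._events(10), h2)["abundance_per_min"]
        assert a2 == pytest.approx(a1 / 2)

    def test_empty_events(self):
        h = Hypnogram(states=["NREM"] * 30)
        s = spindle_summary([], h)
        assert s["abundance_per_min"] == 0.0
        assert np.isnan(s["mean_duration"])

    def test_zero_nrem_time_undefined(self):
        h = Hypnogram(states=["Wake"] * 30)
        assert np.isnan(spindle_summary([], h)["abundance_per_min"])


class TestSpikes:
    def test_planted_transients_counted_exactly(self):
        sim = simulate_eeg(PlantedEEGSpec(spindle_rate=0.0), seed=7)
        events = detect_spikes(sim.recording)
        assert len(events) == len(sim.spike_times)
        det = np.sort([e.time for e in events])
        np.testing.assert_allclose(det, np.sort(sim.spike_times), atol=0.05)

    def test_zero_signal_gives_no_events(self):
        rec = make_recording(np.zeros(5000))
        assert detect_spikes(rec) == []

    def test_gaussian_noise_false_positives_below_one_per_hour(self):
        rng = np.random.default_rng(10)
        rec = make_recording(rng.normal(0, 10, int(3600 * 200)), fs=200.0)
        events = detect_spikes(rec, threshold_sd=7.0)
        assert len(events) < 1

    def test_invalid_threshold_rejected(self):
        rec = make_recording(np.zeros(1000))
        with pytest.raises(ValueError):
            detect_spikes(rec, threshold_sd=0.0)
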