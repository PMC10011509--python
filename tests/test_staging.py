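"""Staging features, the classification cascade, and sleep metrics."""

import numpy as np
import pandas as pd
import pytest

from mouseeg import sigio, staging, synthgen
from mouseeg.exceptions import ClassificationError, ParameterError

FS = 1000.0


def _grid(n_epochs):
    return [(k * 10000, (k + 1) * 10000) for k in range(n_epochs)]


class TestEpochFeatures:
    def test_delta_tone_dominates_delta_band(self):
        t = np.arange(10000) / FS
        eeg = np.tile(np.sin(2 * np.pi * 2.0 * t), 1)
        feats = staging.epoch_features(eeg, np.zeros_like(eeg), FS, _grid(1))
        row = feats.iloc[0]
        assert row["delta"] == max(row["delta"], row["theta"], row["sigma"], row["gamma"])

    def test_emg_rms_closed_form(self):
        rng = np.random.default_rng(0)
        r = 25.0
        emg = rng.standard_normal(10000) * r
        expected = float(np.sqrt(np.mean(emg**2)))
        t = np.arange(10000) / FS
        feats = staging.epoch_features(np.sin(2 * np.pi * 3 * t), emg, FS, _grid(1))
        assert feats["emg_rms"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert feats["emg_rms"].iloc[0] == pytest.approx(r, rel=0.03)

    def test_noise_entropy_exceeds_tone_entropy(self):
        rng = np.random.default_rng(1)
        t = np.arange(10000) / FS
        eeg = np.concatenate([rng.standard_normal(10000), np.sin(2 * np.pi * 6 * t)])
        feats = staging.epoch_features(eeg, np.zeros_like(eeg), FS, _grid(2))
        assert feats["entropy"].iloc[0] > feats["entropy"].iloc[1]

    def test_flat_epoch_flagged(self):
        eeg = np.zeros(20000)
        eeg[10000:] = np.random.default_rng(2).standard_normal(10000)
        feats = staging.epoch_features(eeg, eeg, FS, _grid(2))
        assert bool(feats["flat"].iloc[0]) and not bool(feats["flat"].iloc[1])


class TestClassifyStages:
    def test_accuracy_on_known_session(self, sleep_session):
        hyp, rec, _ = sleep_session
        grid = sigio.epoch_grid(rec, 10.0)
        feats = staging.epoch_features(rec.get("EEG"), rec.get("EMG"), FS, grid)
        est = staging.classify_stages(feats)
        assert np.mean(est.labels == hyp.labels) >= 0.90

    def test_all_wake_session(self):
        hyp = staging.Hypnogram(np.full(60, "WAKE"), 10.0)
        rec, _ = synthgen.synthesize_session(hyp, seed=9)
        grid = sigio.epoch_grid(rec, 10.0)
        feats = staging.epoch_features(rec.get("EEG"), rec.get("EMG"), FS, grid)
        est = staging.classify_stages(feats)
        assert np.mean(est.labels == "WAKE") >= 0.95

    def test_majority_smoother_removes_singletons(self):
        labels = np.array(["NREM"] * 5 + ["WAKE"] + ["NREM"] * 5, dtype="<U4")
        smoothed = staging._majority_smooth(labels)
        assert np.all(smoothed == "NREM")

    def test_rem_after_wake_relabelled(self):
        # craft features: high EMG run, then one REM-like epoch
        n = 80
        feats = pd.DataFrame(
            dict(
                delta=np.ones(n), theta=np.ones(n), sigma=np.ones(n),
                gamma=np.ones(n), theta_delta=np.full(n, 0.1),
                emg_rms=np.full(n, 40.0), entropy=np.full(n, 0.5),
                flat=np.zeros(n, dtype=bool),
            )
        )
        feats.loc[40:, "emg_rms"] = 5.0  # sleep half
        feats.loc[40, "theta_delta"] = 5.0  # REM-like right after wake
        feats.loc[40, "sigma"] = -5.0
        est = staging.classify_stages(feats)
        assert est.labels[40] != "REM"

    def test_too_few_epochs_rejected(self):
        feats = pd.DataFrame(
            dict(delta=[1.0], theta=[1.0], sigma=[1.0], gamma=[1.0],
                 theta_delta=[0.1], emg_rms=[10.0], entropy=[0.5], flat=[False])
        )
        with pytest.raises(ClassificationError):
            staging.classify_stages(feats)

    def test_degenerate_features_rejected(self):
        n = 100
        feats = pd.DataFrame(
            dict(delta=np.ones(n), theta=np.ones(n), sigma=np.ones(n),
                 gamma=np.ones(n), theta_delta=np.ones(n),
                 emg_rms=np.full(n, 10.0), entropy=np.full(n, 0.5),
                 flat=np.zeros(n, dtype=bool))
        )
        with pytest.raises(ClassificationError, match="degenerate"):
            staging.classify_stages(feats)


class TestSleepMetrics:
    def test_alternating_hypnogram(self):
        labels = np.array(["NREM", "WAKE"] * 180, dtype="<U4")
        m = staging.sleep_metrics(staging.Hypnogram(labels, 10.0))
        assert m.pct_nrem == pytest.approx(50.0)
        assert m.mean_bout_len_s["NREM"] == pytest.approx(10.0)

    def test_all_nrem_first_hour_onset_score(self):
        labels = np.array(["NREM"] * 360 + ["WAKE"] * 360, dtype="<U4")
        m = staging.sleep_metrics(staging.Hypnogram(labels, 10.0))
        assert m.sleep_onset_score == pytest.approx(100.0)

    def test_transitions_per_hour(self):
        # 31 alternating runs over 3 h (1080 epochs) -> 30 transitions -> 10/h
        runs = [35] * 30 + [30]
        labels = np.concatenate(
            [np.full(n, "NREM" if i % 2 == 0 else "WAKE") for i, n in enumerate(runs)]
        ).astype("<U4")
        m = staging.sleep_metrics(staging.Hypnogram(labels, 10.0))
        assert m.transitions_per_hour == pytest.approx(10.0)

    def test_percentages_sum_to_100(self, sleep_session):
        hyp, _, _ = sleep_session
        m = staging.sleep_metrics(hyp)
        assert m.pct_wake + m.pct_nrem + m.pct_rem == pytest.approx(100.0)

    def test_empty_window_rejected(self):
        hyp = staging.Hypnogram(np.full(10, "WAKE"), 10.0)
        with pytest.raises(ParameterError):
            staging.sleep_metrics(hyp, light_cycle_window=(200.0, 100.0))

    def test_hypnogram_round_trip(self, tmp_path, sleep_session):
        hyp, _, _ = sleep_session
        path = staging.write_hypnogram(hyp, tmp_path / "h.tsv")
        back = staging.read_hypnogram(path)
        assert np.array_equal(back.labels, hyp.labels)
        assert np.array_equal(back.light_mask, hyp.light_mask)
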