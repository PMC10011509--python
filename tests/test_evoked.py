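"""Epoching, ASSR power ratios, difference waveforms, and peak finding."""

import numpy as np
import pandas as pd
import pytest

from mouseeg import evoked, sigio, synthgen
from mouseeg.exceptions import ParameterError

FS = 1000.0


def _recording(data):
    return sigio.Recording(np.vstack([data]), FS, ["EEG"])


def _events(onsets, label="tone"):
    return pd.DataFrame({"onset_s": onsets, "label": label})


class TestEpochEvents:
    def test_constant_offset_removed_by_baseline(self):
        rec = _recording(np.full(int(20 * FS), 42.0))
        eps = evoked.epoch_events(
            rec, _events([5.0, 10.0]), -0.1, 0.4, baseline_window=(-0.05, 0.0)
        )
        assert np.abs(eps.data).max() < 1e-9

    def test_edge_trials_dropped_and_counted(self):
        rec = _recording(np.zeros(int(20 * FS)))
        onsets = [0.2, *np.arange(1.0, 19.0, 0.5), 19.9]
        eps = evoked.epoch_events(rec, _events(onsets), -0.5, 1.0)
        assert eps.n_dropped_edge == 2
        assert eps.n_trials == len(onsets) - 2

    def test_artifact_trial_rejected(self):
        x = np.random.default_rng(0).normal(scale=20.0, size=int(20 * FS))
        x[int(10.1 * FS)] = 500.0
        rec = _recording(x)
        eps = evoked.epoch_events(
            rec, _events([5.0, 10.0, 15.0]), -0.1, 0.4, reject_uv=400.0
        )
        assert eps.n_rejected == 1
        assert eps.n_trials == 2


@pytest.fixture(scope="module")
def null_session():
    rec, events = synthgen.generate_assr_session(
        stim_freqs=(50.0,), n_trains_per_freq=100, entrainment_gain=0.0, seed=13
    )
    return evoked.epoch_events(rec, events, -0.5, 1.0, reject_uv=None)


class TestAssrRatio:
    def test_no_signal_ratio_near_one(self, null_session):
        assert evoked.assr_power_ratio(null_session, 50.0) == pytest.approx(
            1.0, abs=0.15
        )

    def test_off_frequency_ratio_near_one(self):
        wake = synthgen.DEFAULT_STAGE_PARAMS["WAKE"]
        gain = synthgen.gain_for_power_excess(wake, 50.0, 3.0)
        rec, events = synthgen.generate_assr_session(
            stim_freqs=(50.0,), n_trains_per_freq=100, entrainment_gain=gain, seed=14
        )
        eps = evoked.epoch_events(rec, events, -0.5, 1.0, reject_uv=None)
        assert evoked.assr_power_ratio(eps, 50.0) > 3.0
        # same trials, read out at unstimulated frequencies (null sd ~ 0.1)
        untagged = evoked.Epochs(eps.data, eps.times, FS, eps.labels)
        off = [evoked.assr_power_ratio(untagged, f) for f in (20.0, 30.0)]
        assert np.mean(off) == pytest.approx(1.0, abs=0.2)
        assert all(abs(r - 1.0) < 0.35 for r in off)

    def test_amplitude_scale_invariance(self, null_session):
        scaled = evoked.Epochs(
            7.5 * null_session.data, null_session.times, FS, null_session.labels
        )
        assert evoked.assr_power_ratio(scaled, 50.0) == pytest.approx(
            evoked.assr_power_ratio(null_session, 50.0), rel=1e-9
        )

    def test_unresolvable_frequency_rejected(self, null_session):
        with pytest.raises(ParameterError):
            evoked.assr_power_ratio(null_session, 43.0)  # 2-Hz grid, off-bin

    def test_window_too_short_rejected(self):
        eps = evoked.Epochs(
            np.zeros((3, 500)), np.arange(500) / FS, FS, np.array(["a"] * 3)
        )
        with pytest.raises(ParameterError):
            evoked.assr_power_ratio(eps, 40.0)


class TestErp:
    def _template_erp(self, components=synthgen.DEFAULT_DEVIANT_COMPONENTS, sign=1.0):
        t = np.arange(-100, 400) / FS
        wave = sign * synthgen._component_sum(components, t)
        return evoked.Erp(wave, t, 100, "x")

    def test_identical_inputs_zero_difference(self):
        erp = self._template_erp()
        diff = evoked.erp_difference(erp, erp)
        assert np.abs(diff.waveform).max() == 0.0

    def test_difference_is_linear(self):
        std = self._template_erp(synthgen.DEFAULT_STANDARD_COMPONENTS)
        dev = self._template_erp(synthgen.DEFAULT_DEVIANT_COMPONENTS)
        diff = evoked.erp_difference(std, dev)
        bump = dev.waveform - std.waveform
        assert np.allclose(diff.waveform, bump)

    def test_grid_mismatch_rejected(self):
        a = self._template_erp()
        b = evoked.Erp(a.waveform[:-1], a.times[:-1], 10, "y")
        with pytest.raises(ParameterError):
            evoked.erp_difference(a, b)

    def test_peak_recovery_from_template(self):
        peaks = evoked.find_erp_peaks(self._template_erp())
        for comp, spec in (("P1", 18.0), ("N1", 50.0), ("P3a", 180.0)):
            assert peaks.found(comp)
            assert abs(peaks.latency_ms(comp) - spec) <= 5.0
        assert peaks.amplitude("P1") == pytest.approx(25.0, rel=0.10)
        assert peaks.amplitude("N1") == pytest.approx(-40.0, rel=0.10)
        assert peaks.amplitude("P3a") == pytest.approx(60.0, rel=0.10)

    def test_polarity_contract_on_inverted_bump(self):
        t = np.arange(0, 400) / FS
        bump = 10.0 * np.exp(-((t - 0.040) ** 2) / (2 * 0.008**2))
        windows = {"P1": (0.010, 0.080), "N1": (0.010, 0.080), "P3a": (0.1, 0.3)}
        up = evoked.find_erp_peaks(evoked.Erp(bump, t, 1, "u"), windows)
        down = evoked.find_erp_peaks(evoked.Erp(-bump, t, 1, "d"), windows)
        assert up.found("P1") and abs(up.latency_ms("P1") - 40.0) < 1.0
        assert not down.found("P1")
        assert down.found("N1") and abs(down.latency_ms("N1") - 40.0) < 1.0

    def test_flat_waveform_all_absent(self):
        t = np.arange(-100, 400) / FS
        peaks = evoked.find_erp_peaks(evoked.Erp(np.zeros(t.size), t, 1, "z"))
        assert not any(peaks.found(c) for c in ("P1", "N1", "P3a"))

    def test_averaging_noise_shrinks_with_sqrt_trials(self):
        rng = np.random.default_rng(5)
        rec = _recording(rng.standard_normal(int(220 * FS)))
        onsets = np.arange(1.0, 201.0, 1.0)
        eps = evoked.epoch_events(rec, _events(onsets), -0.1, 0.4, reject_uv=None)
        small = evoked.Epochs(eps.data[:25], eps.times, FS, eps.labels[:25])
        big = evoked.Epochs(eps.data[:100], eps.times, FS, eps.labels[:100])
        ratio = evoked.average_erp(small).waveform.std() / evoked.average_erp(
            big
        ).waveform.std()
        assert ratio == pytest.approx(2.0, rel=0.35)
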