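"""Generator ground truth: hypnogram fractions, PSD shape, events, templates."""

import dataclasses

import numpy as np
import pytest

from mouseeg import evoked, sigio, spectra, staging, synthgen
from mouseeg.exceptions import ParameterError

FS = 1000.0


class TestHypnogram:
    def test_degenerate_all_nrem(self):
        hyp = synthgen.generate_hypnogram(600.0, target_nrem_fraction=1.0, seed=0)
        assert np.all(hyp.labels == "NREM")

    def test_realized_fraction_12h(self):
        hyp = synthgen.generate_hypnogram(
            12 * 3600.0, target_nrem_fraction=0.50, seed=3
        )
        assert 0.47 <= hyp.fraction("NREM") <= 0.53

    def test_realized_fraction_24h_light_cycle(self):
        hyp = synthgen.generate_hypnogram(
            24 * 3600.0, target_nrem_fraction=0.55, seed=4
        )
        assert abs(hyp.fraction("NREM", light_only=True) - 0.55) <= 0.03
        assert hyp.light_mask.sum() == 12 * 360  # first 12 h

    def test_sleep_onset_latency(self):
        hyp = synthgen.generate_hypnogram(
            1200.0, sleep_onset_latency_s=600.0, seed=5
        )
        assert np.all(hyp.labels[:60] == "WAKE")
        assert hyp.labels[60] == "NREM"

    def test_infeasible_target_raises(self):
        with pytest.raises(ParameterError, match="unreachable"):
            synthgen.generate_hypnogram(3600.0, target_nrem_fraction=0.98, seed=0)

    def test_duration_not_on_grid_raises(self):
        with pytest.raises(ParameterError):
            synthgen.generate_hypnogram(605.0, seed=0)


class TestSynthesizeSession:
    def test_seed_reproducibility(self, sleep_session):
        hyp, rec, truth = sleep_session
        rec2, truth2 = synthgen.synthesize_session(hyp, seed=7)
        assert np.array_equal(rec.data, rec2.data)
        assert [e.onset_s for e in truth] == [e.onset_s for e in truth2]

    def test_aperiodic_slope_recovered(self, aperiodic_only_params):
        hyp = staging.Hypnogram(np.full(30, "NREM"), 10.0)
        rec, _ = synthgen.synthesize_session(
            hyp, aperiodic_only_params, synthgen.SpindleGenParams(rates={}), seed=1
        )
        fit = spectra.fit_aperiodic(spectra.welch_psd(rec.get("EEG"), FS))
        assert fit.exponent == pytest.approx(2.0, abs=0.15)

    def test_parseval_calibration(self, sleep_session):
        """Epoch variance matches the Welch PSD integral (ensemble and session).

        Individual 10-s epochs of steep 1/f signals carry too few slow
        cycles for a tight per-epoch bound, so calibration is asserted on
        the epoch ensemble mean and on the full session.
        """
        _, rec, _ = sleep_session
        eeg = rec.get("EEG")
        ratios = []
        for s, e in sigio.epoch_grid(rec, 10.0):
            epoch = eeg[s:e]
            spec = spectra.welch_psd(epoch, FS)
            ratios.append(epoch.var() / np.trapezoid(spec.psd, spec.freqs))
        assert abs(np.mean(ratios) - 1.0) <= 0.05
        assert 0.75 <= min(ratios) and max(ratios) <= 1.35
        full = spectra.welch_psd(eeg, FS)
        session_ratio = eeg.var() / np.trapezoid(full.psd, full.freqs)
        assert abs(session_ratio - 1.0) <= 0.05

    def test_spindle_count_matches_rate(self, nrem_only_session):
        _, _, truth = nrem_only_session
        # rate 5/min over 10 pure-NREM minutes: ~50 events, counting noise
        assert 50 - 4 * np.sqrt(50) <= len(truth) <= 50 + 4 * np.sqrt(50)

    def test_spindles_inside_nrem(self, sleep_session):
        hyp, _, truth = sleep_session
        step = 10.0
        for ev in truth:
            assert hyp.labels[int(ev.onset_s // step)] == "NREM"
            assert hyp.labels[int((ev.offset_s - 1e-9) // step)] == "NREM"

    def test_gamma_amplitude_to_power_squaring(self):
        """Amplitude x1.2 on the gamma peak yields ~1.44x gamma band power."""
        base = synthgen.StageParams(-2.0, 1.0, (synthgen.OscPeak(40.0, 2.0, 5.0),), 10.0)
        boosted = synthgen.StageParams(
            -2.0, 1.0, (synthgen.OscPeak(40.0, 2.4, 5.0),), 10.0
        )
        hyp = staging.Hypnogram(np.full(30, "NREM"), 10.0)
        powers = []
        for params in (base, boosted):
            stage_params = {s: params for s in ("WAKE", "NREM", "REM")}
            stage_params["WAKE"] = dataclasses.replace(params, emg_rms_uv=40.0)
            rec, _ = synthgen.synthesize_session(
                hyp, stage_params, synthgen.SpindleGenParams(rates={}), seed=6
            )
            spec = spectra.welch_psd(rec.get("EEG"), FS)
            powers.append(spectra.band_power(spec, "gamma"))
        assert powers[1] / powers[0] == pytest.approx(1.44, rel=0.03)

    def test_gamma_power_scale_is_exact_in_model(self):
        params = synthgen.DEFAULT_STAGE_PARAMS["NREM"]
        scaled = synthgen.apply_gamma_power_scale(params, 1.2)
        band = (30.0, 50.0)
        ratio = synthgen.band_power_model(scaled, band) / synthgen.band_power_model(
            params, band
        )
        assert ratio == pytest.approx(1.2, abs=1e-9)


class TestAssrSession:
    def test_event_table_size_and_order(self):
        rec, events = synthgen.generate_assr_session(
            stim_freqs=(10.0, 40.0), n_trains_per_freq=5, seed=0
        )
        assert len(events) == 10
        assert np.all(np.diff(events["onset_s"]) > 0)
        assert set(events["freq_hz"]) == {10.0, 40.0}
        assert events["onset_s"].iloc[-1] + 1.0 < rec.duration_s

    def test_short_isi_rejected(self):
        with pytest.raises(ParameterError, match="baseline"):
            synthgen.generate_assr_session(isi_s=0.3, seed=0)

    def test_short_train_rejected(self):
        with pytest.raises(ParameterError):
            synthgen.generate_assr_session(train_duration_s=0.8, seed=0)

    def test_calibrated_excess_ratio(self):
        """Gain set for 3x bin power -> evoked/baseline ratio ~ 4."""
        wake = synthgen.DEFAULT_STAGE_PARAMS["WAKE"]
        gain = synthgen.gain_for_power_excess(wake, 50.0, 3.0)
        rec, events = synthgen.generate_assr_session(
            stim_freqs=(50.0,), n_trains_per_freq=100, entrainment_gain=gain, seed=2
        )
        eps = evoked.epoch_events(rec, events, -0.5, 1.0, reject_uv=None)
        assert evoked.assr_power_ratio(eps, 50.0) == pytest.approx(4.0, abs=0.5)


class TestMmnSession:
    def test_trial_counts(self):
        _, events = synthgen.generate_mmn_session(seed=0)
        assert (events["label"] == "standard").sum() == 900
        assert (events["label"] == "deviant").sum() == 100

    def test_no_adjacent_deviants(self):
        _, events = synthgen.generate_mmn_session(seed=1)
        dev = np.flatnonzero((events["label"] == "deviant").to_numpy())
        assert np.all(np.diff(dev) >= 2)

    def test_noiseless_trial_equals_template(self):
        rec, events = synthgen.generate_mmn_session(
            n_standard=27, n_deviant=3, background_params=None, seed=2
        )
        eeg = rec.get("EEG")
        onset = float(events.loc[events["label"] == "deviant", "onset_s"].iloc[0])
        i0 = int(onset * FS)
        t = np.arange(int(0.75 * FS)) / FS
        template = synthgen._component_sum(synthgen.DEFAULT_DEVIANT_COMPONENTS, t)
        assert np.abs(eeg[i0 : i0 + t.size] - template).max() < 1e-9

    def test_p3a_scaling_in_difference_template(self):
        """Scaling the deviant P3a by 0.3 scales the difference-template peak."""
        t = np.arange(int(0.4 * FS)) / FS
        std = synthgen._component_sum(synthgen.DEFAULT_STANDARD_COMPONENTS, t)
        scaled = tuple(
            dataclasses.replace(c, amplitude_uv=0.3 * c.amplitude_uv)
            if c.name == "P3a"
            else c
            for c in synthgen.DEFAULT_DEVIANT_COMPONENTS
        )
        full = synthgen._component_sum(synthgen.DEFAULT_DEVIANT_COMPONENTS, t) - std
        dev = synthgen._component_sum(scaled, t) - std
        win = (t >= 0.1) & (t <= 0.3)
        assert dev[win].max() == pytest.approx(0.3 * full[win].max(), rel=1e-6)

    def test_bad_deviant_fraction_rejected(self):
        with pytest.raises(ParameterError, match="fraction"):
            synthgen.generate_mmn_session(n_standard=100, n_deviant=50, seed=0)

    def test_short_isi_rejected(self):
        with pytest.raises(ParameterError, match="ISI"):
            synthgen.generate_mmn_session(isi_s=0.2, seed=0)


class TestParameterInvariants:
    def test_emg_ordering_enforced(self):
        params = dict(synthgen.DEFAULT_STAGE_PARAMS)
        params["WAKE"] = dataclasses.replace(params["WAKE"], emg_rms_uv=1.0)
        hyp = staging.Hypnogram(np.full(60, "WAKE"), 10.0)
        with pytest.raises(ParameterError, match="EMG"):
            synthgen.synthesize_session(hyp, params, seed=0)

    def test_peak_center_bounds(self):
        with pytest.raises(ParameterError):
            synthgen.OscPeak(150.0, 1.0, 1.0)

    def test_positive_exponent_required(self):
        with pytest.raises(ParameterError):
            synthgen.StageParams(1.0, -0.5)

    def test_spindle_duration_bounds(self):
        with pytest.raises(ParameterError):
            synthgen.SpindleGenParams(duration_range_s=(0.1, 1.0))

    def test_effect_scalings_positive(self):
        with pytest.raises(ParameterError):
            synthgen.EffectConfig(gamma_power=0.0)
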