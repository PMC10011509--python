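"""Ground-truthed synthetic EEG/EMG sessions: sleep, ASSR, and oddball.

The generator emulates 24-h (or shorter) rodent sleep/wake sessions on a
10-s epoch grid, click-train ASSR sessions at 10-50 Hz, and auditory oddball
sessions with a 90/10 standard/deviant split, all sampled at 1000 Hz.

Signal model, per stage:

* EEG background is Gaussian 1/f^chi noise produced by spectral shaping of
  white noise, with one-sided PSD
  ``S(f) = 10**offset * f**-chi + sum_k (A_k**2/2) * N(f; c_k, sigma_k**2)``
  so the band power contributed by an oscillatory peak equals A**2/2 (a
  sinusoid of amplitude A), and the aperiodic exponent matches the model
  fitted downstream.
* Sleep spindles are raised-cosine (Hann) amplitude-modulated sinusoids at
  9/11/13/15 Hz inserted during NREM only, Poisson in time; ground-truth
  onsets are sample-accurate.
* EMG is white noise at a stage-dependent RMS, highest in wake.

Genotype contrasts are injected through :class:`EffectConfig` multiplicative
scalings. Spindle-rate effects are applied by thinning a shared candidate
event stream, and the gamma-power effect is defined on the model's 30-50 Hz
band power (the generator solves for the peak amplitude that achieves the
requested band-power factor exactly), so the injected ground truth equals
the stated relative change.

All randomness flows from one session seed through named child generators
(noise vs. events); fixing the seed reproduces a session bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import ParameterError
from .sigio import Recording
from .spindles import SpindleEvent
from .staging import EPOCH_LEN_S, Hypnogram

logger = logging.getLogger(__name__)

__all__ = [
    "OscPeak",
    "StageParams",
    "SpindleGenParams",
    "ErpComponentSpec",
    "EffectConfig",
    "DEFAULT_STAGE_PARAMS",
    "DEFAULT_SPINDLE_PARAMS",
    "DEFAULT_STANDARD_COMPONENTS",
    "DEFAULT_DEVIANT_COMPONENTS",
    "model_psd",
    "band_power_model",
    "background_rms",
    "apply_gamma_power_scale",
    "generate_hypnogram",
    "synthesize_session",
    "generate_assr_session",
    "gain_for_power_excess",
    "generate_mmn_session",
]

LIGHT_CYCLE_S = 12 * 3600.0


# ---------------------------------------------------------------------------
# parameter types


@dataclass(frozen=True)
class OscPeak:
    """Oscillatory peak: center (Hz), signal amplitude (µV), Gaussian width (Hz)."""

    center_hz: float
    amplitude_uv: float
    bandwidth_hz: float

    def __post_init__(self) -> None:
        if not 0.5 <= self.center_hz <= 100.0:
            raise ParameterError("peak centers must lie within 0.5-100 Hz")
        if self.amplitude_uv < 0 or self.bandwidth_hz <= 0:
            raise ParameterError("peak amplitude must be >= 0 and bandwidth > 0")


@dataclass(frozen=True)
class StageParams:
    """Spectral and EMG parameters of one vigilance stage."""

    offset: float  # log10(µV²/Hz) at 1 Hz
    exponent: float  # chi > 0
    peaks: tuple[OscPeak, ...] = ()
    emg_rms_uv: float = 10.0

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ParameterError("aperiodic exponent chi must be > 0")
        if self.emg_rms_uv < 0:
            raise ParameterError("EMG RMS must be >= 0")
        object.__setattr__(self, "peaks", tuple(self.peaks))


def _check_stage_dict(stage_params: dict[str, StageParams]) -> None:
    for name in ("WAKE", "NREM", "REM"):
        if name not in stage_params:
            raise ParameterError(f"stage parameters missing {name}")
    w = stage_params["WAKE"].emg_rms_uv
    if not (w > stage_params["NREM"].emg_rms_uv and w > stage_params["REM"].emg_rms_uv):
        raise ParameterError("EMG RMS must be highest in WAKE")


#: Stage defaults emulating frontal mouse EEG: steep delta-dominated NREM,
#: theta-dominated low-EMG REM, desynchronized high-EMG wake. All stages
#: carry a broad 40 Hz gamma peak so genotype gamma effects apply per state.
DEFAULT_STAGE_PARAMS: dict[str, StageParams] = {
    "WAKE": StageParams(2.0, 2.0, (OscPeak(7.0, 5.0, 1.0), OscPeak(40.0, 2.0, 5.0)), 40.0),
    "NREM": StageParams(2.5, 2.5, (OscPeak(2.0, 20.0, 0.6), OscPeak(40.0, 2.0, 5.0)), 10.0),
    "REM": StageParams(1.8, 2.2, (OscPeak(7.0, 14.0, 1.0), OscPeak(40.0, 2.0, 5.0)), 5.0),
}


#: Minimum silence between consecutive inserted spindles (s); keeps distinct
#: events separable by a detector that merges gaps shorter than 0.3 s.
SPINDLE_MIN_GAP_S = 0.5


@dataclass(frozen=True)
class SpindleGenParams:
    """Spindle insertion: events per NREM minute at each center frequency.

    ``base_rates`` is the candidate-process rate used for thinning; leaving
    it at None uses ``rates`` (no thinning). Cohort builders set the
    wild-type rates as the shared base so rate effects act by subsetting one
    candidate stream (common random numbers across genotypes).
    """

    rates: dict[float, float] = field(
        default_factory=lambda: {9.0: 2.0, 11.0: 3.0, 13.0: 2.0, 15.0: 1.0}
    )
    duration_range_s: tuple[float, float] = (0.8, 1.6)
    amplitude_uv: float = 12.0
    base_rates: dict[float, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.duration_range_s
        if not 0.3 <= lo <= hi <= 4.0:
            raise ParameterError("spindle durations must lie within [0.3, 4.0] s")
        if any(r < 0 for r in self.rates.values()):
            raise ParameterError("spindle rates must be >= 0")
        if self.amplitude_uv < 0:
            raise ParameterError("spindle amplitude must be >= 0")
        base = self.base_rates if self.base_rates is not None else dict(self.rates)
        for f, r in self.rates.items():
            if base.get(f, 0.0) < r:
                raise ParameterError("base (candidate) rate must be >= thinned rate")
        object.__setattr__(self, "base_rates", base)

    def scaled(self, factor: float) -> "SpindleGenParams":
        """Scale event rates, keeping the candidate base for thinning."""
        if factor <= 0:
            raise ParameterError("rate scale must be > 0")
        base = {
            f: max(self.base_rates[f], self.rates[f] * factor) for f in self.rates
        }
        return SpindleGenParams(
            rates={f: r * factor for f, r in self.rates.items()},
            duration_range_s=self.duration_range_s,
            amplitude_uv=self.amplitude_uv,
            base_rates=base,
        )


@dataclass(frozen=True)
class ErpComponentSpec:
    """One ERP component: a polarity-signed Gaussian bump."""

    name: str
    latency_ms: float
    polarity: int  # +1 or -1
    amplitude_uv: float
    width_ms: float  # Gaussian sigma

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ParameterError("polarity must be +1 or -1")
        if self.width_ms <= 0 or self.amplitude_uv < 0:
            raise ParameterError("width must be > 0 and amplitude >= 0")


DEFAULT_STANDARD_COMPONENTS: tuple[ErpComponentSpec, ...] = (
    ErpComponentSpec("P1", 18.0, +1, 25.0, 6.0),
    ErpComponentSpec("N1", 50.0, -1, 40.0, 10.0),
)
DEFAULT_DEVIANT_COMPONENTS: tuple[ErpComponentSpec, ...] = (
    ErpComponentSpec("P1", 18.0, +1, 25.0, 6.0),
    ErpComponentSpec("N1", 50.0, -1, 40.0, 10.0),
    ErpComponentSpec("P3a", 180.0, +1, 60.0, 35.0),
)


def _check_component_order(components) -> None:
    lat = {c.name: c.latency_ms for c in components}
    order = [lat[n] for n in ("P1", "N1", "P3a") if n in lat]
    if any(a >= b for a, b in zip(order, order[1:])):
        raise ParameterError("component latencies must be ordered P1 < N1 < P3a")


@dataclass(frozen=True)
class EffectConfig:
    """Multiplicative genotype effect scalings on a baseline parameter set.

    ``gamma_power`` scales the model's 30-50 Hz band power (per stage);
    ``spindle_rate`` the insertion rate at every center frequency;
    ``assr_gain`` the entrainment amplitude; ``p3a_amplitude`` the deviant
    P3a component; ``nrem_fraction`` the hypnogram's target NREM fraction.
    """

    gamma_power: float = 1.0
    spindle_rate: float = 1.0
    assr_gain: float = 1.0
    p3a_amplitude: float = 1.0
    nrem_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_power", "spindle_rate", "assr_gain",
                     "p3a_amplitude", "nrem_fraction"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"effect scaling {name} must be > 0")


# ---------------------------------------------------------------------------
# analytic model helpers


def model_psd(params: StageParams, freqs: np.ndarray) -> np.ndarray:
    """One-sided model PSD (µV²/Hz) on a frequency grid; 0 at DC."""
    f = np.asarray(freqs, dtype=float)
    out = np.zeros_like(f)
    pos = f > 0
    out[pos] = 10.0**params.offset * f[pos] ** (-params.exponent)
    for pk in params.peaks:
        out += (
            (pk.amplitude_uv**2 / 2.0)
            * sstats.norm.pdf(f, pk.center_hz, pk.bandwidth_hz)
        )
    return out


def _aperiodic_band_power(params: StageParams, band: tuple[float, float]) -> float:
    lo, hi = band
    b, chi = params.offset, params.exponent
    if abs(chi - 1.0) < 1e-12:
        return 10.0**b * float(np.log(hi / lo))
    return 10.0**b * (hi ** (1 - chi) - lo ** (1 - chi)) / (1 - chi)


def _peak_band_power(pk: OscPeak, band: tuple[float, float]) -> float:
    lo, hi = band
    frac = sstats.norm.cdf(hi, pk.center_hz, pk.bandwidth_hz) - sstats.norm.cdf(
        lo, pk.center_hz, pk.bandwidth_hz
    )
    return pk.amplitude_uv**2 / 2.0 * float(frac)


def band_power_model(params: StageParams, band: tuple[float, float]) -> float:
    """Exact band power (µV²) of the model PSD over a band."""
    return _aperiodic_band_power(params, band) + sum(
        _peak_band_power(pk, band) for pk in params.peaks
    )


def background_rms(params: StageParams, f_range: tuple[float, float] = (0.5, 100.0)) -> float:
    """RMS (µV) of the stage's model over a frequency range."""
    return float(np.sqrt(band_power_model(params, f_range)))


def apply_gamma_power_scale(
    params: StageParams, factor: float, band: tuple[float, float] = (30.0, 50.0)
) -> StageParams:
    """Rescale the gamma peak so the model's band power changes by ``factor``.

    Solves A' = A * sqrt(P_peak' / P_peak) with
    P_peak' = factor * (P_aperiodic + P_peak) - P_aperiodic, so the injected
    relative band-power change is exact in the model.
    """
    if factor == 1.0:
        return params
    in_band = [pk for pk in params.peaks if band[0] <= pk.center_hz <= band[1]]
    if not in_band:
        raise ParameterError("no oscillatory peak inside the gamma band to scale")
    p_ap = _aperiodic_band_power(params, band)
    p_pk = sum(_peak_band_power(pk, band) for pk in in_band)
    p_new = factor * (p_ap + p_pk) - p_ap
    if p_new <= 0 or p_pk <= 0:
        raise ParameterError(
            f"band-power factor {factor} infeasible: peak power would be {p_new:.3g}"
        )
    amp_scale = float(np.sqrt(p_new / p_pk))
    new_peaks = tuple(
        replace(pk, amplitude_uv=pk.amplitude_uv * amp_scale) if pk in in_band else pk
        for pk in params.peaks
    )
    return replace(params, peaks=new_peaks)


#: Emulated acquisition band (Hz): the EEG front-end band-passes the signal,
#: so synthesized noise carries no power outside this range. The lower edge
#: sits below the slowest analysed band (slow oscillations, 0.5-1 Hz).
ACQ_BAND = (0.5, 100.0)


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, params: StageParams) -> np.ndarray:
    """Gaussian noise with the stage's one-sided PSD, via spectral shaping.

    Power outside :data:`ACQ_BAND` is zeroed, emulating the acquisition
    bandpass; this also keeps the 1/f model integrable so epoch variance
    matches the PSD integral (Parseval).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    psd = model_psd(params, f)
    psd[(f < ACQ_BAND[0]) | (f > ACQ_BAND[1])] = 0.0
    amp = np.sqrt(psd * fs / 2.0)
    return np.fft.irfft(spec * amp, n)


# ---------------------------------------------------------------------------
# hypnogram generation


def generate_hypnogram(
    duration_s: float,
    stage_bout_means: dict[str, float] | None = None,
    target_nrem_fraction: float = 0.55,
    sleep_onset_latency_s: float = 0.0,
    seed: int = 0,
    target_rem_fraction: float | None = None,
    epoch_len_s: float = EPOCH_LEN_S,
    fraction_tol: float = 0.03,
    max_tries: int = 50,
) -> Hypnogram:
    """Semi-Markov WAKE/NREM/REM sequence on a fixed epoch grid.

    The chain cycles WAKE -> NREM -> (REM with probability q) -> WAKE with
    geometric bout lengths. The NREM and REM bout means are taken from
    ``stage_bout_means``; the effective wake bout mean is solved so the
    expected NREM fraction equals the target (infeasible combinations raise
    :class:`ParameterError`). Candidate sequences are redrawn (deterministic
    substreams of ``seed``) until the realized light-cycle NREM fraction is
    within ``fraction_tol`` of the target; the closest draw is kept if none
    qualifies.

    The session starts with exactly ``sleep_onset_latency_s`` of wake
    (rounded to the epoch grid) followed by the first NREM bout.
    """
    L = epoch_len_s
    n_total = int(round(duration_s / L))
    if abs(n_total * L - duration_s) > 1e-6:
        raise ParameterError("duration_s must be a multiple of the epoch length")
    if not 0 < target_nrem_fraction <= 1:
        raise ParameterError("target NREM fraction must lie in (0, 1]")
    means = dict(stage_bout_means or {"WAKE": 120.0, "NREM": 100.0, "REM": 60.0})
    for stage in ("NREM", "REM"):
        if means.get(stage, 0.0) <= L:
            raise ParameterError(f"{stage} bout mean must exceed the epoch length")

    n_latency = int(round(sleep_onset_latency_s / L))
    if n_latency >= n_total:
        raise ParameterError("sleep-onset latency exceeds the session")

    light = np.arange(n_total) * L < LIGHT_CYCLE_S

    if target_nrem_fraction >= 1.0 - 1e-9:
        labels = np.full(n_total, "NREM", dtype="<U4")
        labels[:n_latency] = "WAKE"
        return Hypnogram(labels, L, light)

    f_n = target_nrem_fraction
    f_r = (
        target_rem_fraction
        if target_rem_fraction is not None
        else 0.15 * target_nrem_fraction
    )
    m_n, m_r = means["NREM"], means["REM"]
    q = f_r * m_n / (f_n * m_r) if f_r > 0 else 0.0
    if q > 1.0:
        raise ParameterError(
            "REM fraction unreachable: would need REM after every NREM bout"
        )
    m_w = m_n / f_n - m_n - q * m_r
    if m_w < L:
        raise ParameterError(
            f"target NREM fraction {f_n} unreachable with bout means {means}"
        )

    def draw(rng: np.random.Generator) -> np.ndarray:
        labels = ["WAKE"] * n_latency
        state = "NREM"
        while len(labels) < n_total:
            mean = {"WAKE": m_w, "NREM": m_n, "REM": m_r}[state]
            k = rng.geometric(min(1.0, L / mean))
            labels.extend([state] * k)
            if state == "WAKE":
                state = "NREM"
            elif state == "NREM":
                state = "REM" if rng.uniform() < q else "WAKE"
            else:
                state = "WAKE"
        return np.asarray(labels[:n_total], dtype="<U4")

    streams = np.random.SeedSequence(seed).spawn(max_tries)
    best, best_err = None, np.inf
    for child in streams:
        labels = draw(np.random.default_rng(child))
        realized = float(np.mean(labels[light] == "NREM"))
        err = abs(realized - f_n)
        if err < best_err:
            best, best_err = labels, err
        if err <= fraction_tol:
            break
    return Hypnogram(best, L, light)


# ---------------------------------------------------------------------------
# sleep-session synthesis


def _stage_runs(hypnogram: Hypnogram, fs: float):
    """Yield (stage, start_sample, n_samples) for maximal same-stage runs."""
    step = int(round(hypnogram.epoch_len_s * fs))
    labels = hypnogram.labels
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            yield labels[start], start * step, (i - start) * step
            start = i


def synthesize_session(
    hypnogram: Hypnogram,
    stage_params: dict[str, StageParams] | None = None,
    spindle_params: SpindleGenParams | None = None,
    fs: float = 1000.0,
    seed: int = 0,
    meta: dict | None = None,
) -> tuple[Recording, list[SpindleEvent]]:
    """Render a hypnogram into an EEG+EMG recording with ground-truth spindles.

    Noise and event randomness come from separate named substreams of
    ``seed`` so parameter scalings that alter amplitudes (but not event
    draws) leave the noise realization untouched.
    """
    if fs < 200:
        raise ParameterError("sampling rate must be >= 200 Hz")
    stage_params = dict(stage_params or DEFAULT_STAGE_PARAMS)
    _check_stage_dict(stage_params)
    spindle_params = spindle_params if spindle_params is not None else DEFAULT_SPINDLE_PARAMS

    ss = np.random.SeedSequence(seed)
    noise_ss, event_ss = ss.spawn(2)
    rng_noise = np.random.default_rng(noise_ss)
    rng_events = np.random.default_rng(event_ss)

    n_samples = int(round(hypnogram.duration_s * fs))
    eeg = np.empty(n_samples)
    emg = np.empty(n_samples)
    events: list[SpindleEvent] = []
    n_skipped = 0

    for stage, start, length in _stage_runs(hypnogram, fs):
        params = stage_params[stage]
        eeg[start : start + length] = _shaped_noise(rng_noise, length, fs, params)
        emg[start : start + length] = (
            rng_noise.standard_normal(length) * params.emg_rms_uv
        )
        if stage != "NREM" or spindle_params is None:
            continue
        run_dur = length / fs
        d_lo, d_hi = spindle_params.duration_range_s
        d_mean = 0.5 * (d_lo + d_hi)
        g_min = SPINDLE_MIN_GAP_S
        for center in sorted(spindle_params.rates):
            base = spindle_params.base_rates[center]
            rate = spindle_params.rates[center]
            if base <= 0:
                continue
            # Refractory renewal candidate process at the base rate: silence
            # gaps of at least g_min keep distinct events from being merged
            # by an envelope detector, and the mean cycle length equals
            # 60/base so the realized rate matches the nominal rate. Thinning
            # with the shared base keeps a lower-rate cohort's events a
            # strict subset of its pair's (common random numbers).
            theta = 60.0 / base - d_mean - g_min
            if theta <= 0:
                raise ParameterError(
                    f"spindle rate {base}/min too high for {g_min}-s refractory gaps"
                )
            onset = rng_events.uniform(0.0, 60.0 / base)
            while onset < run_dur:
                dur = rng_events.uniform(d_lo, d_hi)
                phi = rng_events.uniform(0.0, 2 * np.pi)
                u = rng_events.uniform()
                gap = g_min + rng_events.exponential(theta)
                this_onset, onset = onset, onset + dur + gap
                if this_onset + dur > run_dur:
                    n_skipped += 1
                    continue
                if u >= rate / base:
                    continue
                i0 = start + int(round(this_onset * fs))
                n_ev = int(round(dur * fs))
                t = np.arange(n_ev) / fs
                env = 0.5 * (1 - np.cos(2 * np.pi * t / (n_ev / fs)))
                eeg[i0 : i0 + n_ev] += (
                    spindle_params.amplitude_uv
                    * env
                    * np.sin(2 * np.pi * center * t + phi)
                )
                events.append(
                    SpindleEvent(
                        onset_s=i0 / fs,
                        offset_s=(i0 + n_ev) / fs,
                        center_hz=center,
                        peak_amp_uv=spindle_params.amplitude_uv,
                        mean_amp_uv=spindle_params.amplitude_uv / 2.0,
                    )
                )
    if n_skipped:
        logger.debug("skipped %d spindles exceeding their NREM bout", n_skipped)

    events.sort(key=lambda ev: ev.onset_s)
    rec = Recording(
        np.vstack([eeg, emg]), fs, ["EEG", "EMG"], meta=dict(meta or {})
    )
    return rec, events


DEFAULT_SPINDLE_PARAMS = SpindleGenParams()


# ---------------------------------------------------------------------------
# ASSR sessions


def gain_for_power_excess(
    background_params: StageParams,
    freq_hz: float,
    excess: float,
    window_s: float = 0.5,
) -> float:
    """Entrainment gain making the evoked/baseline ratio ~ ``1 + excess``.

    With a Hann-windowed Welch estimate of window T, an on-bin sinusoid of
    amplitude A contributes a bin density of (A**2/2) / ENBW with
    ENBW = 1.5 / T, so A = sqrt(2 * excess * ENBW * S_bg(f)). The returned
    gain is A relative to the background RMS (the amplitude convention of
    :func:`generate_assr_session`).
    """
    if excess <= 0:
        raise ParameterError("excess must be > 0")
    enbw = 1.5 / window_s
    s_bg = float(model_psd(background_params, np.array([freq_hz]))[0])
    amp = float(np.sqrt(2.0 * excess * enbw * s_bg))
    return amp / background_rms(background_params)


def generate_assr_session(
    stim_freqs: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0),
    n_trains_per_freq: int = 60,
    train_duration_s: float = 1.0,
    entrainment_gain: float | dict[float, float] = 0.08,
    background_params: StageParams | None = None,
    isi_s: float = 1.5,
    fs: float = 1000.0,
    seed: int = 0,
    meta: dict | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Click-train entrainment session: sinusoidal steady-state responses.

    During each train a sinusoid at the stimulation frequency with amplitude
    ``gain * background RMS`` is added from onset to offset; trains of the
    different frequencies are presented in randomized order with ``isi_s``
    of silence between them (>= 0.5 s so the pre-stimulus baseline is clean).
    """
    if train_duration_s < 1.0:
        raise ParameterError("train duration must be >= 1 s for the evoked window")
    if isi_s < 0.5:
        raise ParameterError(
            "inter-train interval < 0.5 s would overlap the next baseline"
        )
    bg = background_params or DEFAULT_STAGE_PARAMS["WAKE"]
    gains = (
        dict(entrainment_gain)
        if isinstance(entrainment_gain, dict)
        else {f: float(entrainment_gain) for f in stim_freqs}
    )
    for f in stim_freqs:
        if f >= fs / 2:
            raise ParameterError("stimulation frequency above Nyquist")
        if gains.get(f, 0.0) < 0:
            raise ParameterError("entrainment gain must be >= 0")

    ss = np.random.SeedSequence(seed)
    noise_ss, order_ss = ss.spawn(2)
    rng_order = np.random.default_rng(order_ss)

    order = np.repeat(np.asarray(stim_freqs, dtype=float), n_trains_per_freq)
    rng_order.shuffle(order)

    lead_in = 2.0
    spacing = train_duration_s + isi_s
    duration = float(np.ceil(lead_in + order.size * spacing + 1.0))
    n = int(round(duration * fs))
    eeg = _shaped_noise(np.random.default_rng(noise_ss), n, fs, bg)
    emg = np.random.default_rng(noise_ss.spawn(1)[0]).standard_normal(n) * bg.emg_rms_uv

    rms = background_rms(bg)
    onsets = lead_in + np.arange(order.size) * spacing
    n_train = int(round(train_duration_s * fs))
    t = np.arange(n_train) / fs
    for onset, f in zip(onsets, order):
        i0 = int(round(onset * fs))
        eeg[i0 : i0 + n_train] += gains[f] * rms * np.sin(2 * np.pi * f * t)

    events = pd.DataFrame(
        {"onset_s": onsets, "label": "assr", "freq_hz": order}
    )
    rec = Recording(np.vstack([eeg, emg]), fs, ["EEG", "EMG"], meta=dict(meta or {}))
    return rec, events


# ---------------------------------------------------------------------------
# oddball (MMN) sessions


def _component_sum(
    components, times_s: np.ndarray
) -> np.ndarray:
    out = np.zeros_like(times_s)
    for c in components:
        sigma = c.width_ms / 1000.0
        lat = c.latency_ms / 1000.0
        out += (
            c.polarity
            * c.amplitude_uv
            * np.exp(-((times_s - lat) ** 2) / (2 * sigma**2))
        )
    return out


def generate_mmn_session(
    n_standard: int = 900,
    n_deviant: int = 100,
    components_standard=DEFAULT_STANDARD_COMPONENTS,
    components_deviant=DEFAULT_DEVIANT_COMPONENTS,
    isi_s: float = 0.75,
    background_params: StageParams | None = DEFAULT_STAGE_PARAMS["WAKE"],
    fs: float = 1000.0,
    seed: int = 0,
    meta: dict | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Auditory oddball session: 90% standard / 10% deviant tone responses.

    Each event adds its condition's component sum (polarity-signed Gaussian
    bumps) to the ongoing background. Deviants are placed uniformly at
    random subject to at least one standard between consecutive deviants.
    Pass ``background_params=None`` for a noiseless session (template
    verification).
    """
    total = n_standard + n_deviant
    frac = n_deviant / total
    if not 0.05 <= frac <= 0.15:
        raise ParameterError(
            f"deviant fraction {frac:.3f} outside the oddball regime (~0.1)"
        )
    _check_component_order(components_standard)
    _check_component_order(components_deviant)
    t_required = max(
        (c.latency_ms + 3 * c.width_ms) / 1000.0
        for c in (*components_standard, *components_deviant)
    )
    if isi_s < t_required:
        raise ParameterError(
            f"ISI {isi_s} s shorter than the longest component span "
            f"({t_required:.3f} s)"
        )

    ss = np.random.SeedSequence(seed)
    noise_ss, seq_ss = ss.spawn(2)
    rng_seq = np.random.default_rng(seq_ss)

    # Stars-and-bars placement: pick n_deviant of the n_standard+1 slots
    # between (or flanking) standards, guaranteeing non-adjacent deviants.
    slots = np.sort(rng_seq.choice(n_standard + 1, size=n_deviant, replace=False))
    labels = []
    d = 0
    for s in range(n_standard + 1):
        if d < n_deviant and slots[d] == s:
            labels.append("deviant")
            d += 1
        if s < n_standard:
            labels.append("standard")
    labels = np.asarray(labels)

    lead_in = 2.0
    onsets = lead_in + np.arange(total) * isi_s
    duration = float(np.ceil(lead_in + total * isi_s + 1.0))
    n = int(round(duration * fs))

    if background_params is not None:
        eeg = _shaped_noise(np.random.default_rng(noise_ss), n, fs, background_params)
        emg = (
            np.random.default_rng(noise_ss.spawn(1)[0]).standard_normal(n)
            * background_params.emg_rms_uv
        )
    else:
        eeg = np.zeros(n)
        emg = np.zeros(n)

    n_resp = int(round(isi_s * fs))
    t_resp = np.arange(n_resp) / fs
    templates = {
        "standard": _component_sum(components_standard, t_resp),
        "deviant": _component_sum(components_deviant, t_resp),
    }
    for onset, label in zip(onsets, labels):
        i0 = int(round(onset * fs))
        eeg[i0 : i0 + n_resp] += templates[label]

    events = pd.DataFrame({"onset_s": onsets, "label": labels})
    rec = Recording(np.vstack([eeg, emg]), fs, ["EEG", "EMG"], meta=dict(meta or {}))
    return rec, events
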