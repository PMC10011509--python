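"""Evoked analyses: ASSR entrainment power ratios and oddball (MMN) ERPs.

ASSR entrainment is quantified as the ratio of Welch power at the
stimulation frequency in the evoked window (0.2-1 s post-stimulus) over the
pre-stimulus baseline (-0.5-0 s), with Welch window 0.5 s and overlap
0.25 s; per-segment PSDs are averaged across trials before the ratio is
taken (lower variance than averaging per-trial ratios).

MMN analysis averages baseline-corrected trials per condition, forms the
deviant-minus-standard difference waveform, and reads P1/N1/P3a peaks in
ordered search windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ParameterError
from .sigio import Recording

__all__ = [
    "Epochs",
    "Erp",
    "PeakSet",
    "DEFAULT_PEAK_WINDOWS",
    "epoch_events",
    "average_erp",
    "assr_power_ratio",
    "erp_difference",
    "find_erp_peaks",
]

#: Mouse-typical ERP component search windows (s post-stimulus).
DEFAULT_PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "P1": (0.010, 0.050),
    "N1": (0.030, 0.100),
    "P3a": (0.100, 0.300),
}


@dataclass
class Epochs:
    """Per-trial windowed signal matrix around stimulus events."""

    data: np.ndarray  # (n_trials, n_samples), µV
    times: np.ndarray  # s relative to stimulus
    fs: float
    labels: np.ndarray  # per-trial condition label
    stim_freq_hz: np.ndarray | None = None  # per-trial, for ASSR sessions
    n_dropped_edge: int = 0
    n_rejected: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, label: str) -> "Epochs":
        m = self.labels == label
        return Epochs(
            self.data[m], self.times, self.fs, self.labels[m],
            None if self.stim_freq_hz is None else self.stim_freq_hz[m],
        )


@dataclass
class Erp:
    """Trial-averaged, baseline-corrected waveform for one condition."""

    waveform: np.ndarray
    times: np.ndarray
    n_trials: int
    condition: str = ""


@dataclass
class PeakSet:
    """Per-component peak latency/amplitude read from an ERP."""

    peaks: dict = field(default_factory=dict)
    # component -> dict(latency_s, amplitude_uv, window, found)

    def amplitude(self, component: str) -> float:
        return self.peaks[component]["amplitude_uv"]

    def latency_ms(self, component: str) -> float:
        return 1000.0 * self.peaks[component]["latency_s"]

    def found(self, component: str) -> bool:
        return self.peaks[component]["found"]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(component=c, latency_ms=1000.0 * v["latency_s"],
                     amplitude_uv=v["amplitude_uv"], found=v["found"])
                for c, v in self.peaks.items()
            ]
        )


def epoch_events(
    recording: Recording,
    events: pd.DataFrame,
    t_min: float,
    t_max: float,
    channel: str = "EEG",
    baseline_window: tuple[float, float] | None = None,
    reject_uv: float | None = 400.0,
) -> Epochs:
    """Slice per-trial windows around events with baseline correction.

    Trials too close to the recording edges are dropped (counted in
    ``n_dropped_edge``); trials whose absolute amplitude after baseline
    correction exceeds ``reject_uv`` are rejected (``n_rejected``).
    """
    if t_min >= t_max:
        raise ParameterError("t_min must be < t_max")
    x = recording.get(channel)
    fs = recording.fs
    i_min = int(round(t_min * fs))
    i_max = int(round(t_max * fs))
    n_win = i_max - i_min
    times = (np.arange(n_win) + i_min) / fs

    rows, labels, freqs = [], [], []
    dropped = 0
    has_freq = "freq_hz" in events
    for _, ev in events.iterrows():
        center = int(round(float(ev["onset_s"]) * fs))
        lo, hi = center + i_min, center + i_max
        if lo < 0 or hi > x.size:
            dropped += 1
            continue
        rows.append(x[lo:hi])
        labels.append(str(ev["label"]))
        if has_freq:
            freqs.append(float(ev["freq_hz"]))
    data = np.array(rows, dtype=float).reshape(len(rows), n_win)
    labels = np.asarray(labels)
    freq_arr = np.asarray(freqs) if has_freq else None

    if baseline_window is not None:
        b_lo, b_hi = baseline_window
        bmask = (times >= b_lo) & (times < b_hi)
        if not bmask.any():
            raise ParameterError("baseline window outside the epoch")
        data = data - data[:, bmask].mean(axis=1, keepdims=True)

    rejected = 0
    if reject_uv is not None and data.size:
        keep = np.abs(data).max(axis=1) <= reject_uv
        rejected = int((~keep).sum())
        data = data[keep]
        labels = labels[keep]
        if freq_arr is not None:
            freq_arr = freq_arr[keep]

    return Epochs(data, times, fs, labels, freq_arr, dropped, rejected)


def average_erp(epochs: Epochs, condition: str | None = None) -> Erp:
    """Average trials (optionally of one condition) into an ERP."""
    ep = epochs if condition is None else epochs.select(condition)
    if ep.n_trials < 1:
        raise ParameterError("cannot average zero trials")
    return Erp(ep.data.mean(axis=0), ep.times, ep.n_trials, condition or "all")


def assr_power_ratio(
    epochs: Epochs,
    stim_freq_hz: float,
    window_s: float = 0.5,
    overlap_s: float = 0.25,
    evoked_window: tuple[float, float] = (0.2, 1.0),
    baseline_window: tuple[float, float] = (-0.5, 0.0),
) -> float:
    """Evoked/baseline power ratio at the stimulation frequency."""
    t = epochs.times
    if t[0] > baseline_window[0] + 1e-9 or t[-1] < evoked_window[1] - 1 / epochs.fs:
        raise ParameterError("epoch window must cover [-0.5, 1.0] s")
    if epochs.stim_freq_hz is not None:
        sel = epochs.data[np.isclose(epochs.stim_freq_hz, stim_freq_hz)]
    else:
        sel = epochs.data
    if sel.shape[0] == 0:
        raise ParameterError(f"no trials at {stim_freq_hz} Hz")

    def mean_psd(win: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
        m = (t >= win[0]) & (t < win[1])
        seg = sel[:, m]
        nperseg = int(round(window_s * epochs.fs))
        if seg.shape[1] < nperseg:
            raise ParameterError("analysis window shorter than the Welch window")
        f, p = sps.welch(
            seg, fs=epochs.fs, window="hann", nperseg=nperseg,
            noverlap=int(round(overlap_s * epochs.fs)), detrend="constant", axis=-1,
        )
        return f, p.mean(axis=0)

    f_ev, p_ev = mean_psd(evoked_window)
    f_bl, p_bl = mean_psd(baseline_window)
    if stim_freq_hz > f_ev[-1]:
        raise ParameterError(f"{stim_freq_hz} Hz outside the resolvable grid")
    df = f_ev[1] - f_ev[0]
    k = int(np.argmin(np.abs(f_ev - stim_freq_hz)))
    if abs(f_ev[k] - stim_freq_hz) > df / 2 + 1e-9:
        raise ParameterError(f"{stim_freq_hz} Hz not resolvable on the PSD grid")
    k_bl = int(np.argmin(np.abs(f_bl - stim_freq_hz)))
    if p_bl[k_bl] <= 0:
        raise ParameterError("zero baseline power at the stimulation frequency")
    return float(p_ev[k] / p_bl[k_bl])


def erp_difference(erp_standard: Erp, erp_deviant: Erp) -> Erp:
    """Pointwise deviant - standard difference waveform."""
    if erp_standard.times.shape != erp_deviant.times.shape or not np.allclose(
        erp_standard.times, erp_deviant.times
    ):
        raise ParameterError("ERPs are not on the same time grid")
    return Erp(
        erp_deviant.waveform - erp_standard.waveform,
        erp_standard.times,
        min(erp_standard.n_trials, erp_deviant.n_trials),
        "difference",
    )


def _extremum(
    wave: np.ndarray, times: np.ndarray, window: tuple[float, float],
    sign: int, after_s: float | None,
) -> tuple[float, float, bool]:
    lo = window[0] if after_s is None else max(window[0], after_s)
    m = (times >= lo) & (times <= window[1])
    if m.sum() < 3:
        return float("nan"), float("nan"), False
    seg = sign * wave[m]
    tseg = times[m]
    i = int(np.argmax(seg))
    amp = sign * seg[i]
    # an extremum at the window edge of a monotone segment is not a peak
    interior = 0 < i < seg.size - 1
    found = bool(interior and abs(amp) > 0)
    return float(tseg[i]), float(amp), found


def find_erp_peaks(
    erp: Erp, windows: dict[str, tuple[float, float]] | None = None
) -> PeakSet:
    """Locate P1 (positive), N1 (negative, after P1) and P3a (positive,
    after N1) on a baseline-corrected waveform.

    Components without an interior extremum (monotone or flat segments) are
    flagged absent; their latency constraint then does not gate later
    components.
    """
    windows = dict(DEFAULT_PEAK_WINDOWS if windows is None else windows)
    wave, times = erp.waveform, erp.times
    out = PeakSet()

    lat_p1, amp_p1, ok_p1 = _extremum(wave, times, windows["P1"], +1, None)
    out.peaks["P1"] = dict(
        latency_s=lat_p1, amplitude_uv=amp_p1, window=windows["P1"], found=ok_p1
    )
    lat_n1, amp_n1, ok_n1 = _extremum(
        wave, times, windows["N1"], -1, lat_p1 if ok_p1 else None
    )
    out.peaks["N1"] = dict(
        latency_s=lat_n1, amplitude_uv=amp_n1, window=windows["N1"], found=ok_n1
    )
    lat_p3, amp_p3, ok_p3 = _extremum(
        wave, times, windows["P3a"], +1, lat_n1 if ok_n1 else None
    )
    out.peaks["P3a"] = dict(
        latency_s=lat_p3, amplitude_uv=amp_p3, window=windows["P3a"], found=ok_p3
    )
    return out
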