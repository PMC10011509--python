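"""Sleep-spindle detection at discrete center frequencies during NREM.

Detector: narrowband filter at center +/- 1 Hz, analytic envelope, 0.2-s
moving-RMS smoothing, then a median-relative two-threshold rule: candidate
events start where the envelope exceeds 3x the NREM median, boundaries
extend to the 1.5x-median crossings, events closer than 0.3 s are merged,
and survivors are kept when 0.5-3.0 s long and fully inside NREM. Median
thresholds make detection invariant to per-subject amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ParameterError
from .sigio import bandpass_array
from .staging import Hypnogram

__all__ = [
    "SPINDLE_FREQS",
    "SpindleEvent",
    "detect_spindles",
    "spindle_density",
    "events_to_frame",
]

#: Center frequencies (Hz) at which spindle density is reported.
SPINDLE_FREQS = (9.0, 11.0, 13.0, 15.0)


@dataclass
class SpindleEvent:
    onset_s: float
    offset_s: float
    center_hz: float
    peak_amp_uv: float
    mean_amp_uv: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _moving_rms(x: np.ndarray, n: int) -> np.ndarray:
    kernel = np.ones(n) / n
    return np.sqrt(np.convolve(x**2, kernel, mode="same"))


def detect_spindles(
    eeg: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    center_hz: float,
    half_bw_hz: float = 1.0,
    threshold_hi: float = 3.0,
    threshold_lo: float = 1.5,
    merge_gap_s: float = 0.3,
    min_dur_s: float = 0.5,
    max_dur_s: float = 3.0,
    smooth_s: float = 0.2,
) -> list[SpindleEvent]:
    """Detect spindle events at one center frequency during NREM sleep."""
    eeg = np.asarray(eeg, dtype=float)
    if not 0 < center_hz - half_bw_hz < center_hz + half_bw_hz < fs / 2:
        raise ParameterError("spindle band must lie within (0, fs/2)")
    nrem = hypnogram.sample_mask("NREM", fs, eeg.size)
    if not nrem.any():
        raise ParameterError("no NREM epochs in the hypnogram")

    narrow = bandpass_array(eeg, fs, center_hz - half_bw_hz, center_hz + half_bw_hz)
    env = np.abs(sps.hilbert(narrow))
    env = _moving_rms(env, max(1, int(round(smooth_s * fs))))

    med = float(np.median(env[nrem]))
    if med <= 0:
        raise ParameterError("zero median NREM envelope; cannot set thresholds")
    hi, lo = threshold_hi * med, threshold_lo * med

    above_hi = env > hi
    above_lo = env > lo
    cand = np.flatnonzero(above_hi & nrem)
    if cand.size == 0:
        return []

    # Seed intervals from contiguous high-threshold runs, then widen each to
    # the surrounding low-threshold crossings.
    seeds = []
    start = cand[0]
    prev = cand[0]
    for i in cand[1:]:
        if i != prev + 1:
            seeds.append((start, prev))
            start = i
        prev = i
    seeds.append((start, prev))

    intervals = []
    for s, e in seeds:
        while s > 0 and above_lo[s - 1]:
            s -= 1
        while e < env.size - 1 and above_lo[e + 1]:
            e += 1
        intervals.append([s, e])

    merged = [intervals[0]]
    gap = merge_gap_s * fs
    for s, e in intervals[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        dur = (e - s + 1) / fs
        if not min_dur_s <= dur <= max_dur_s:
            continue
        if not nrem[s : e + 1].all():
            continue
        seg = env[s : e + 1]
        events.append(
            SpindleEvent(
                onset_s=s / fs,
                offset_s=(e + 1) / fs,
                center_hz=center_hz,
                peak_amp_uv=float(seg.max()),
                mean_amp_uv=float(seg.mean()),
            )
        )
    return events


def spindle_density(
    events: list[SpindleEvent], hypnogram: Hypnogram, light_only: bool = True
) -> float:
    """Events per NREM minute (light-cycle NREM by default).

    Only events whose onset falls inside a counted NREM epoch contribute.
    """
    counted = (hypnogram.labels == "NREM") & (
        hypnogram.light_mask if light_only else True
    )
    minutes = counted.sum() * hypnogram.epoch_len_s / 60.0
    if minutes <= 0:
        raise ParameterError("zero NREM time; density undefined")
    L = hypnogram.epoch_len_s
    n = sum(
        1
        for ev in events
        if 0 <= int(ev.onset_s // L) < counted.size and counted[int(ev.onset_s // L)]
    )
    return n / minutes


def events_to_frame(events: list[SpindleEvent]) -> pd.DataFrame:
    """One row per event, suitable for tab-delimited export."""
    return pd.DataFrame(
        [
            dict(
                onset_s=ev.onset_s,
                offset_s=ev.offset_s,
                center_hz=ev.center_hz,
                peak_amp_uv=ev.peak_amp_uv,
                mean_amp_uv=ev.mean_amp_uv,
            )
            for ev in events
        ],
        columns=["onset_s", "offset_s", "center_hz", "peak_amp_uv", "mean_amp_uv"],
    )
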