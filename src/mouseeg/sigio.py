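"""Signal I/O and shared preprocessing.

Recordings travel on disk as EDF (European Data Format), the open standard
for polysomnography; event tables and hypnograms are tab-delimited text.
The EDF codec here implements the 16-bit continuous-recording subset of the
format (one data record per second, physical scaling from the header).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import FormatError, ParameterError

__all__ = [
    "Recording",
    "read_edf",
    "write_edf",
    "bandpass",
    "bandpass_array",
    "epoch_grid",
    "read_events",
    "write_events",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class Recording:
    """Multichannel time series in physical units (microvolts).

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Samples in µV.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel names, typically ``["EEG", "EMG"]``.
    start_time : datetime, optional
        Session start; defaults to a fixed epoch so synthetic sessions are
        byte-reproducible.
    meta : dict
        Session metadata (``subject_id``, ``genotype``, ``age_label`` ...).
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 7, 0, 0)
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ParameterError(
                f"{self.data.shape[0]} rows for {len(self.channels)} channel names"
            )
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ParameterError("recording contains NaNs; gaps must be explicit")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def get(self, channel: str) -> np.ndarray:
        try:
            idx = self.channels.index(channel)
        except ValueError:
            raise ParameterError(
                f"channel {channel!r} not in {self.channels}"
            ) from None
        return self.data[idx]


def _pad_ascii(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width, b" ")


def _meta_to_patient_field(meta: dict) -> str:
    parts = []
    for key in ("subject_id", "genotype", "age_label"):
        val = meta.get(key)
        if val is not None:
            parts.append(f"{key}={val}")
    return " ".join(parts) if parts else "X"


def _patient_field_to_meta(text: str) -> dict:
    meta: dict = {}
    for token in text.split():
        if "=" in token:
            key, val = token.split("=", 1)
            meta[key] = val
    return meta


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a Recording to EDF with 1-second data records.

    The sampling rate must be a positive integer and the signal length a
    whole number of seconds (the generator always produces such sessions).
    Samples are quantized to 16 bits over each channel's observed range.
    """
    path = Path(path)
    fs = recording.fs
    if fs != int(fs) or fs <= 0:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_samples = recording.n_samples
    if n_samples % fs != 0:
        raise ParameterError(
            "signal length must be a whole number of seconds for EDF export"
        )
    n_records = n_samples // fs
    n_chan = len(recording.channels)

    phys_min = recording.data.min(axis=1)
    phys_max = recording.data.max(axis=1)
    # Guard degenerate (constant) channels with a non-zero span.
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    start = recording.start_time
    header = b"".join(
        [
            _pad_ascii("0", 8),
            _pad_ascii(_meta_to_patient_field(recording.meta), 80),
            _pad_ascii("Startdate X mouseeg", 80),
            _pad_ascii(start.strftime("%d.%m.%y"), 8),
            _pad_ascii(start.strftime("%H.%M.%S"), 8),
            _pad_ascii(str(256 * (1 + n_chan)), 8),
            _pad_ascii("", 44),
            _pad_ascii(str(n_records), 8),
            _pad_ascii("1", 8),
            _pad_ascii(str(n_chan), 4),
        ]
    )
    header += b"".join(_pad_ascii(c, 16) for c in recording.channels)
    header += b"".join(_pad_ascii("", 80) for _ in range(n_chan))
    header += b"".join(_pad_ascii("uV", 8) for _ in range(n_chan))
    header += b"".join(_pad_ascii(f"{v:.8g}"[:8], 8) for v in phys_min)
    header += b"".join(_pad_ascii(f"{v:.8g}"[:8], 8) for v in phys_max)
    header += b"".join(_pad_ascii(str(_DIG_MIN), 8) for _ in range(n_chan))
    header += b"".join(_pad_ascii(str(_DIG_MAX), 8) for _ in range(n_chan))
    header += b"".join(_pad_ascii("", 80) for _ in range(n_chan))
    header += b"".join(_pad_ascii(str(fs), 8) for _ in range(n_chan))
    header += b"".join(_pad_ascii("", 32) for _ in range(n_chan))

    # Re-read the header strings we actually wrote so quantization uses the
    # same (possibly truncated) physical bounds the reader will see.
    pmin_txt = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax_txt = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    gain = (pmax_txt - pmin_txt) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((recording.data - pmin_txt[:, None]) / gain[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # record-interleaved layout: (n_records, n_chan, fs)
        interleaved = digital.reshape(n_chan, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(interleaved).tobytes())
    return path


def _read_field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset : offset + width].decode("ascii", errors="replace").strip()


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording in physical units (µV).

    Raises :class:`FormatError` on corrupt headers, truncated data, or
    channels with differing durations (all channels must share the sampling
    rate used by this pipeline).
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: file shorter than an EDF header")
    try:
        header_bytes = int(_read_field(raw, 184, 8))
        n_records = int(_read_field(raw, 236, 8))
        record_dur = float(_read_field(raw, 244, 8))
        n_chan = int(_read_field(raw, 252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: corrupt EDF header ({exc})") from None
    if n_chan < 1:
        raise FormatError(f"{path}: header declares {n_chan} channels")
    if len(raw) < header_bytes:
        raise FormatError(f"{path}: truncated header")

    sig = raw[256:header_bytes]

    def sig_field(block: int, width: int, idx: int) -> str:
        start = block + idx * width
        return sig[start : start + width].decode("ascii", errors="replace").strip()

    # Field blocks in declaration order, offsets relative to byte 256.
    off_label = 0
    off_dim = n_chan * (16 + 80)
    off_pmin = off_dim + n_chan * 8
    off_pmax = off_pmin + n_chan * 8
    off_dmin = off_pmax + n_chan * 8
    off_dmax = off_dmin + n_chan * 8
    off_nsamp = off_dmax + n_chan * 8 + n_chan * 80

    channels, pmin, pmax, dmin, dmax, nsamp = [], [], [], [], [], []
    try:
        for i in range(n_chan):
            channels.append(sig_field(off_label, 16, i))
            pmin.append(float(sig_field(off_pmin, 8, i)))
            pmax.append(float(sig_field(off_pmax, 8, i)))
            dmin.append(int(sig_field(off_dmin, 8, i)))
            dmax.append(int(sig_field(off_dmax, 8, i)))
            nsamp.append(int(sig_field(off_nsamp, 8, i)))
    except ValueError as exc:
        raise FormatError(f"{path}: corrupt signal header ({exc})") from None

    if len(set(nsamp)) != 1:
        raise FormatError(
            f"{path}: channels declare differing samples/record {nsamp}; "
            f"first offender: {channels[int(np.argmax(nsamp != nsamp[0]))]}"
        )
    spr = nsamp[0]
    expected = header_bytes + n_records * n_chan * spr * 2
    if len(raw) < expected:
        raise FormatError(
            f"{path}: truncated data ({len(raw)} bytes, expected {expected})"
        )

    data16 = np.frombuffer(
        raw, dtype="<i2", count=n_records * n_chan * spr, offset=header_bytes
    )
    data16 = data16.reshape(n_records, n_chan, spr).transpose(1, 0, 2)
    data16 = data16.reshape(n_chan, n_records * spr)

    out = np.empty(data16.shape, dtype=float)
    for i in range(n_chan):
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        out[i] = (data16[i].astype(float) - dmin[i]) * gain + pmin[i]

    try:
        day = _read_field(raw, 168, 8)
        tod = _read_field(raw, 176, 8)
        start = _dt.datetime.strptime(day + " " + tod, "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = _dt.datetime(2000, 1, 1)

    return Recording(
        data=out,
        fs=spr / record_dur,
        channels=channels,
        start_time=start,
        meta=_patient_field_to_meta(_read_field(raw, 8, 80)),
    )


def bandpass_array(
    x: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward, SOS form)."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < fs/2"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def bandpass(
    recording: Recording, channel: str, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Filter one channel of a recording; returns samples, same length."""
    return bandpass_array(recording.get(channel), recording.fs, low_hz, high_hz, order)


def epoch_grid(recording: Recording | int, epoch_len_s: float, fs: float | None = None):
    """Contiguous half-open sample intervals tiling a recording.

    Epoch ``k`` covers samples ``[k*L*fs, (k+1)*L*fs)``; a trailing partial
    epoch is dropped. Accepts either a Recording or a sample count plus
    ``fs``.
    """
    if epoch_len_s <= 0:
        raise ParameterError("epoch_len_s must be positive")
    if isinstance(recording, Recording):
        n_samples, fs = recording.n_samples, recording.fs
    else:
        n_samples = int(recording)
        if fs is None:
            raise ParameterError("fs is required when passing a sample count")
    step = int(round(epoch_len_s * fs))
    n_epochs = n_samples // step
    return [(k * step, (k + 1) * step) for k in range(n_epochs)]


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    """Write an event table (onset_s, label[, freq_hz]) as tab-delimited text."""
    path = Path(path)
    cols = ["onset_s", "label"] + (["freq_hz"] if "freq_hz" in events else [])
    events.to_csv(path, sep="\t", index=False, columns=cols)
    return path


def read_events(path: str | Path, duration_s: float | None = None) -> pd.DataFrame:
    """Read an event table, validating ordering and (optionally) bounds."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - normalize to the format contract
        raise FormatError(f"{path}: unreadable event table ({exc})") from None
    if "onset_s" not in df or "label" not in df:
        raise FormatError(f"{path}: event table needs onset_s and label columns")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise FormatError(f"{path}: event onsets are not sorted ascending")
    if duration_s is not None and onsets.size and onsets[-1] > duration_s:
        raise FormatError(f"{path}: event beyond recording end ({onsets[-1]:.2f} s)")
    return df
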