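"""Sleep staging: per-epoch WAKE/NREM/REM classification and sleep metrics.

Each 10-s epoch is classified from EEG band powers and EMG tone with a
transparent rule cascade using per-recording adaptive thresholds:

1. WAKE when the epoch's EMG RMS falls in the high cluster of a two-cluster
   split of log EMG RMS (muscle tone is strongly bimodal between wake and
   sleep). A fixed quantile would pin the labelled wake fraction, so the
   cluster split is used instead; when the EMG distribution is unimodal the
   recording is treated as single-state and resolved from the EEG.
2. Among sleep epochs, REM when theta/delta power ratio exceeds a threshold
   (default 1.5) and sigma power lies below the median of sleep candidates
   (REM lacks spindle-band power).
3. NREM otherwise.

Labels are then smoothed with a 3-epoch majority filter and REM epochs
immediately following WAKE are relabelled WAKE (the wake-to-REM transition
is not physiological in healthy rodents).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ClassificationError, FormatError, ParameterError
from .spectra import band_power, spectral_entropy, welch_psd

__all__ = [
    "STAGES",
    "Hypnogram",
    "SleepMetrics",
    "epoch_features",
    "classify_stages",
    "sleep_metrics",
    "read_hypnogram",
    "write_hypnogram",
]

STAGES = ("WAKE", "NREM", "REM")

#: Default epoch length (s); the rodent sleep-scoring convention.
EPOCH_LEN_S = 10.0


@dataclass
class Hypnogram:
    """Per-epoch stage labels on a fixed epoch grid."""

    labels: np.ndarray  # dtype <U4, values in STAGES
    epoch_len_s: float = EPOCH_LEN_S
    light_mask: np.ndarray | None = None  # True for light-cycle epochs

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U4")
        bad = set(np.unique(self.labels)) - set(STAGES)
        if bad:
            raise ParameterError(f"unknown stage labels {sorted(bad)}")
        if self.light_mask is None:
            self.light_mask = np.ones(self.labels.size, dtype=bool)
        else:
            self.light_mask = np.asarray(self.light_mask, dtype=bool)
            if self.light_mask.size != self.labels.size:
                raise ParameterError("light mask length must match label count")

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def fraction(self, stage: str, light_only: bool = False) -> float:
        labels = self.labels[self.light_mask] if light_only else self.labels
        if labels.size == 0:
            raise ParameterError("empty hypnogram window")
        return float(np.mean(labels == stage))

    def sample_mask(self, stage: str, fs: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask for one stage."""
        mask = np.zeros(n_samples, dtype=bool)
        step = int(round(self.epoch_len_s * fs))
        for k in np.flatnonzero(self.labels == stage):
            mask[k * step : min((k + 1) * step, n_samples)] = True
        return mask


@dataclass
class SleepMetrics:
    """Stage percentages and architecture metrics over an analysis window."""

    pct_wake: float
    pct_nrem: float
    pct_rem: float
    sleep_onset_score: float  # % asleep (NREM or REM) in the first hour
    bout_counts: dict = field(default_factory=dict)
    mean_bout_len_s: dict = field(default_factory=dict)
    transitions_per_hour: float = 0.0

    def as_dict(self) -> dict:
        out = {
            "pct_wake": self.pct_wake,
            "pct_nrem": self.pct_nrem,
            "pct_rem": self.pct_rem,
            "sleep_onset_score": self.sleep_onset_score,
            "transitions_per_hour": self.transitions_per_hour,
        }
        for stage in STAGES:
            out[f"bouts_{stage.lower()}"] = self.bout_counts.get(stage, 0)
            out[f"mean_bout_s_{stage.lower()}"] = self.mean_bout_len_s.get(
                stage, float("nan")
            )
        return out


# ---------------------------------------------------------------------------
# features


def epoch_features(
    eeg: np.ndarray,
    emg: np.ndarray,
    fs: float,
    grid: list[tuple[int, int]],
    window_s: float = 4.0,
    overlap_s: float = 2.0,
) -> pd.DataFrame:
    """Per-epoch staging features.

    Columns: log10 band powers (delta/theta/sigma/gamma), theta/delta ratio,
    EMG RMS (µV), normalized spectral entropy, and a ``flat`` flag for
    all-zero epochs (excluded from thresholding downstream).
    """
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if grid and grid[-1][1] > eeg.size:
        raise ParameterError("epoch grid extends beyond the signal")
    rows = []
    tiny = 1e-12
    for start, end in grid:
        xe = eeg[start:end]
        xm = emg[start:end]
        # constant (or all-zero) EEG carries no spectral information
        if np.ptp(xe) == 0:
            rows.append(
                dict(delta=np.nan, theta=np.nan, sigma=np.nan, gamma=np.nan,
                     theta_delta=np.nan, emg_rms=float(np.sqrt(np.mean(xm**2))),
                     entropy=np.nan, flat=True)
            )
            continue
        spec = welch_psd(xe, fs, window_s, overlap_s)
        p_delta = band_power(spec, "delta")
        p_theta = band_power(spec, "theta")
        p_sigma = band_power(spec, "sigma")
        p_gamma = band_power(spec, "gamma")
        rows.append(
            dict(
                delta=np.log10(p_delta + tiny),
                theta=np.log10(p_theta + tiny),
                sigma=np.log10(p_sigma + tiny),
                gamma=np.log10(p_gamma + tiny),
                theta_delta=(p_theta + tiny) / (p_delta + tiny),
                emg_rms=float(np.sqrt(np.mean(xm**2))),
                entropy=spectral_entropy(spec),
                flat=False,
            )
        )
    df = pd.DataFrame(rows)
    good = ~df["flat"]
    if good.any() and not np.isfinite(
        df.loc[good, ["delta", "theta", "sigma", "gamma", "entropy"]].to_numpy()
    ).all():
        raise ClassificationError("non-finite features on non-flat epochs")
    return df


# ---------------------------------------------------------------------------
# classification


def _two_means_split(x: np.ndarray, n_iter: int = 100) -> tuple[float, float]:
    """1-D 2-means on x, seeded at the 30th/70th percentiles."""
    lo, hi = np.percentile(x, [30, 70])
    if lo == hi:
        return float(lo), float(hi)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        low_group = x[x <= mid]
        high_group = x[x > mid]
        if low_group.size == 0 or high_group.size == 0:
            break
        new_lo, new_hi = float(low_group.mean()), float(high_group.mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return lo, hi


def _majority_smooth(labels: np.ndarray) -> np.ndarray:
    """3-epoch sliding majority vote; ties keep the center label."""
    out = labels.copy()
    for i in range(1, labels.size - 1):
        window = labels[i - 1 : i + 2]
        vals, counts = np.unique(window, return_counts=True)
        if counts.max() >= 2:
            out[i] = vals[np.argmax(counts)]
    return out


def classify_stages(
    features: pd.DataFrame,
    epoch_len_s: float = EPOCH_LEN_S,
    theta_delta_rem: float = 1.5,
    emg_separation_ratio: float = 2.0,
    light_mask: np.ndarray | None = None,
) -> Hypnogram:
    """Classify epochs into WAKE/NREM/REM from an epoch-feature table.

    Requires at least 60 epochs so the adaptive thresholds have support.
    Raises :class:`ClassificationError` on degenerate (constant) features.
    """
    if len(features) < 60:
        raise ClassificationError(
            f"need >= 60 epochs for adaptive thresholds, got {len(features)}"
        )
    good = ~features["flat"].to_numpy(dtype=bool)
    if good.sum() < 60:
        raise ClassificationError("too few non-flat epochs")
    emg = features["emg_rms"].to_numpy(dtype=float)
    if np.std(emg[good]) == 0 and np.std(
        features.loc[good, "theta_delta"].to_numpy()
    ) == 0:
        raise ClassificationError("degenerate feature variance (constant signal)")

    log_emg = np.log(np.maximum(emg, 1e-12))
    c_lo, c_hi = _two_means_split(log_emg[good])

    labels = np.full(len(features), "WAKE", dtype="<U4")
    if c_hi - c_lo >= np.log(emg_separation_ratio):
        wake = log_emg > 0.5 * (c_lo + c_hi)
    else:
        # Unimodal muscle tone: the whole recording sits in one vigilance
        # regime. Muscle tone on par with the cortical signal indicates
        # sustained waking; otherwise stage from the EEG cascade alone.
        eeg_rms = np.sqrt(
            10 ** features.loc[good, "delta"].to_numpy(dtype=float)
            + 10 ** features.loc[good, "theta"].to_numpy(dtype=float)
        )
        all_wake = np.median(emg[good]) > np.median(eeg_rms)
        wake = np.full(len(features), all_wake)

    sleep = good & ~wake
    labels[good & wake] = "WAKE"
    if sleep.any():
        td = features["theta_delta"].to_numpy(dtype=float)
        sigma = features["sigma"].to_numpy(dtype=float)
        sigma_med = float(np.median(sigma[sleep]))
        rem = sleep & (td > theta_delta_rem) & (sigma < sigma_med)
        labels[sleep] = "NREM"
        labels[rem] = "REM"

    labels = _majority_smooth(labels)
    for i in range(1, labels.size):
        if labels[i] == "REM" and labels[i - 1] == "WAKE":
            labels[i] = "WAKE"
    return Hypnogram(labels, epoch_len_s, light_mask)


# ---------------------------------------------------------------------------
# metrics


def _runs(labels: np.ndarray):
    """Yield (stage, start, length) for maximal same-stage runs."""
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            yield labels[start], start, i - start
            start = i


def sleep_metrics(
    hypnogram: Hypnogram, light_cycle_window: tuple[float, float] | None = None
) -> SleepMetrics:
    """Stage percentages, sleep-onset score, bouts, and fragmentation.

    ``light_cycle_window`` is (start_s, end_s) within the session; the
    default is the hypnogram's light mask (generator sessions mark the first
    12 h, or the whole session if shorter, as the light cycle).
    """
    L = hypnogram.epoch_len_s
    if light_cycle_window is None:
        idx = np.flatnonzero(hypnogram.light_mask)
    else:
        lo, hi = light_cycle_window
        if not 0 <= lo < hi <= hypnogram.duration_s + 1e-9:
            raise ParameterError("light cycle window outside the session")
        idx = np.arange(int(round(lo / L)), int(round(hi / L)))
    if idx.size == 0:
        raise ParameterError("empty analysis window")
    labels = hypnogram.labels[idx]

    pct = {s: 100.0 * float(np.mean(labels == s)) for s in STAGES}
    first_hour = labels[: max(1, int(round(3600.0 / L)))]
    onset = 100.0 * float(np.mean(np.isin(first_hour, ("NREM", "REM"))))

    bout_counts: dict[str, int] = {s: 0 for s in STAGES}
    bout_lens: dict[str, list[float]] = {s: [] for s in STAGES}
    n_trans = -1
    for stage, _, length in _runs(labels):
        bout_counts[stage] += 1
        bout_lens[stage].append(length * L)
        n_trans += 1
    hours = labels.size * L / 3600.0
    return SleepMetrics(
        pct_wake=pct["WAKE"],
        pct_nrem=pct["NREM"],
        pct_rem=pct["REM"],
        sleep_onset_score=onset,
        bout_counts=bout_counts,
        mean_bout_len_s={
            s: (float(np.mean(v)) if v else float("nan")) for s, v in bout_lens.items()
        },
        transitions_per_hour=max(n_trans, 0) / hours,
    )


# ---------------------------------------------------------------------------
# on-disk form: tab-delimited (epoch_index, stage)


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hypnogram.n_epochs),
            "stage": hypnogram.labels,
            "light": hypnogram.light_mask.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_hypnogram(path: str | Path, epoch_len_s: float = EPOCH_LEN_S) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    if "stage" not in df or "epoch_index" not in df:
        raise FormatError(f"{path}: hypnogram needs epoch_index and stage columns")
    light = (
        df["light"].to_numpy(dtype=bool) if "light" in df else None
    )
    return Hypnogram(df["stage"].to_numpy(), epoch_len_s, light)
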