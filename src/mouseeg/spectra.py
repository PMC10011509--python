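"""Spectral analysis: Welch PSDs, band powers, entropy, 1/f parameterization,
and phase-amplitude coupling.

The aperiodic model is the knee-free form log10 P(f) = b - chi * log10 f; the
exponent chi quantifies the steepness of the 1/f background and the offset b
its level. Oscillatory structure is modelled as Gaussian bumps on top of the
aperiodic line in log-power coordinates, fitted iteratively so the recovered
exponent is not biased by narrowband peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import signal as sps

from .exceptions import ParameterError
from .sigio import bandpass_array

__all__ = [
    "BANDS",
    "Spectrum",
    "AperiodicFit",
    "welch_psd",
    "average_spectra",
    "band_power",
    "spectral_entropy",
    "fit_aperiodic",
    "tort_mi",
    "mi_from_bin_amplitudes",
]

#: Frequency bands (Hz): non-overlapping interiors covering 0.5-50 Hz.
BANDS: dict[str, tuple[float, float]] = {
    "slow": (0.5, 1.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 15.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 50.0),
}


@dataclass
class Spectrum:
    """One-sided power spectral density with its estimation parameters."""

    freqs: np.ndarray  # Hz, ascending
    psd: np.ndarray  # µV²/Hz, >= 0
    window_s: float
    overlap_s: float
    n_segments: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ParameterError("frequency grid must be strictly ascending")
        if np.any(self.psd < 0):
            raise ParameterError("power density must be non-negative")


@dataclass
class AperiodicFit:
    """Result of the iterative aperiodic + peaks parameterization."""

    offset: float  # b, log10(µV²/Hz) at 1 Hz
    exponent: float  # chi
    peaks: list[tuple[float, float, float]]  # (center Hz, height log10, sigma Hz)
    fit_error: float  # MSE in log10-power units
    converged: bool = True


def welch_psd(
    samples: np.ndarray, fs: float, window_s: float = 4.0, overlap_s: float = 2.0
) -> Spectrum:
    """Hann-tapered Welch estimate; the density integrates to ~ the variance."""
    x = np.asarray(samples, dtype=float)
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap_s * fs))
    if not 0 <= noverlap < nperseg:
        raise ParameterError("require 0 <= overlap < window")
    if x.shape[-1] < nperseg:
        raise ParameterError(
            f"signal of {x.shape[-1]} samples shorter than the {nperseg}-sample window"
        )
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, detrend="constant"
    )
    n_segments = 1 + (x.shape[-1] - nperseg) // (nperseg - noverlap)
    return Spectrum(freqs, psd, window_s, overlap_s, n_segments)


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Average PSDs estimated on a common frequency grid."""
    if not spectra:
        raise ParameterError("no spectra to average")
    f0 = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != f0.shape or not np.allclose(s.freqs, f0):
            raise ParameterError("spectra are not on a common frequency grid")
    psd = np.mean([s.psd for s in spectra], axis=0)
    return Spectrum(
        f0, psd, spectra[0].window_s, spectra[0].overlap_s,
        sum(s.n_segments for s in spectra),
    )


def band_power(spectrum: Spectrum, band: str | tuple[float, float]) -> float:
    """Absolute power (µV²): trapezoidal integral of the density over a band.

    Band edges falling between grid points are handled by linear
    interpolation so a flat density of 1 µV²/Hz over a W-Hz band yields
    exactly W µV².
    """
    if isinstance(band, str):
        band = BANDS[band]
    low, high = band
    f, p = spectrum.freqs, spectrum.psd
    if not (low < high):
        raise ParameterError("band must satisfy low < high")
    if low < f[0] or high > f[-1]:
        raise ParameterError(
            f"band ({low}, {high}) outside spectrum range ({f[0]}, {f[-1]})"
        )
    inner = (f > low) & (f < high)
    grid = np.concatenate(([low], f[inner], [high]))
    vals = np.concatenate(([np.interp(low, f, p)], p[inner], [np.interp(high, f, p)]))
    return float(np.trapezoid(vals, grid))


def spectral_entropy(
    spectrum: Spectrum, f_range: tuple[float, float] = (0.5, 50.0)
) -> float:
    """Normalized Shannon entropy of the PSD over a range, in [0, 1].

    1.0 for a flat spectrum, 0.0 for a single occupied bin; invariant to
    multiplicative rescaling.
    """
    mask = (spectrum.freqs >= f_range[0]) & (spectrum.freqs <= f_range[1])
    p = spectrum.psd[mask]
    if p.size < 2:
        raise ParameterError("need at least 2 bins in the entropy range")
    total = p.sum()
    if total <= 0:
        raise ParameterError("all-zero power in the entropy range")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def _gauss(f, center, height, sigma):
    return height * np.exp(-((f - center) ** 2) / (2.0 * sigma**2))


def fit_aperiodic(
    spectrum: Spectrum,
    fit_range: tuple[float, float] = (0.5, 50.0),
    max_peaks: int = 4,
    peak_threshold_sd: float = 2.0,
    n_refits: int = 2,
) -> AperiodicFit:
    """Parameterize a PSD into an aperiodic 1/f component plus Gaussian peaks.

    Iterative procedure in log10-log10 coordinates: line fit, peak detection
    on the residual above ``peak_threshold_sd`` standard deviations, Gaussian
    refinement of each peak, then an aperiodic refit on peak-masked bins
    (repeated ``n_refits`` times). Returns a flagged fit rather than raising
    if the optimizer fails on a peak.
    """
    mask = (spectrum.freqs >= fit_range[0]) & (spectrum.freqs <= fit_range[1])
    f = spectrum.freqs[mask]
    p = spectrum.psd[mask]
    if f.size < 8:
        raise ParameterError("too few bins in the fit range")
    if np.any(p <= 0):
        raise ParameterError("power must be positive throughout the fit range")
    lf = np.log10(f)
    lp = np.log10(p)

    def line_fit(sel: np.ndarray) -> tuple[float, float]:
        slope, intercept = np.polyfit(lf[sel], lp[sel], 1)
        return intercept, -slope  # offset b, exponent chi

    converged = True
    sel = np.ones(f.size, dtype=bool)
    offset, exponent = line_fit(sel)
    peaks: list[tuple[float, float, float]] = []

    for _ in range(n_refits):
        resid = lp - (offset - exponent * lf)
        sd = float(np.std(resid))
        peaks = []
        work = resid.copy()
        df = float(np.median(np.diff(f)))
        for _ in range(max_peaks):
            i = int(np.argmax(work))
            height = work[i]
            if sd == 0 or height < peak_threshold_sd * sd:
                break
            # initial width from the half-maximum span around the apex
            half = height / 2.0
            left = i
            while left > 0 and work[left] > half:
                left -= 1
            right = i
            while right < work.size - 1 and work[right] > half:
                right += 1
            fwhm = max(f[right] - f[left], 2 * df)
            guess = (f[i], height, fwhm / 2.355)
            lo = max(f[0], f[i] - 3 * fwhm)
            hi = min(f[-1], f[i] + 3 * fwhm)
            win = (f >= lo) & (f <= hi)
            try:
                popt, _ = optimize.curve_fit(
                    _gauss, f[win], work[win], p0=guess,
                    bounds=([f[0], 0.0, df / 2], [f[-1], np.inf, (f[-1] - f[0])]),
                    maxfev=2000,
                )
            except (RuntimeError, ValueError):
                popt = guess
                converged = False
            peaks.append((float(popt[0]), float(popt[1]), float(popt[2])))
            work = work - _gauss(f, *popt)
        sel = np.ones(f.size, dtype=bool)
        for center, _, sigma in peaks:
            sel &= np.abs(f - center) > 2.5 * sigma
        if sel.sum() < 4:  # nearly everything masked: fall back to all bins
            sel = np.ones(f.size, dtype=bool)
            converged = False
        offset, exponent = line_fit(sel)

    model = offset - exponent * lf
    for center, height, sigma in peaks:
        model = model + _gauss(f, center, height, sigma)
    fit_error = float(np.mean((lp - model) ** 2))
    return AperiodicFit(offset, exponent, peaks, fit_error, converged)


def tort_mi(
    signal: np.ndarray,
    fs: float,
    phase_band: tuple[float, float] = (1.0, 8.0),
    amp_band: tuple[float, float] = (30.0, 50.0),
    n_bins: int = 18,
) -> float:
    """Phase-amplitude modulation index (KL divergence based), in [0, 1].

    The phase of the slow band and the amplitude envelope of the fast band
    are extracted with the analytic signal; the mean envelope per phase bin
    is normalized to a distribution P and MI = (log N - H(P)) / log N.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 10 * fs:
        raise ParameterError("need at least 10 s of signal for a stable MI")
    for lo, hi in (phase_band, amp_band):
        if not 0 < lo < hi < fs / 2:
            raise ParameterError("bands must lie within (0, fs/2)")
    phase = np.angle(sps.hilbert(bandpass_array(x, fs, *phase_band)))
    amp = np.abs(sps.hilbert(bandpass_array(x, fs, *amp_band)))
    if not np.any(amp > 0):
        raise ParameterError("amplitude envelope is identically zero")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    mean_amp = np.zeros(n_bins)
    for b in range(n_bins):
        m = which == b
        mean_amp[b] = amp[m].mean() if m.any() else 0.0
    return mi_from_bin_amplitudes(mean_amp)


def mi_from_bin_amplitudes(mean_amp: np.ndarray) -> float:
    """MI of a per-phase-bin mean-amplitude profile: (log N - H(P)) / log N.

    1.0 when all amplitude concentrates in a single bin (H = 0), 0.0 for a
    uniform profile.
    """
    mean_amp = np.asarray(mean_amp, dtype=float)
    if mean_amp.ndim != 1 or mean_amp.size < 2 or mean_amp.sum() <= 0:
        raise ParameterError("need a 1-D non-degenerate amplitude profile")
    p = mean_amp / mean_amp.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return float((np.log(p.size) - h) / np.log(p.size))
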