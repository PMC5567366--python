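"""Spectra, spectrograms, and harmonic-structure estimation.

The analysis side of the toolkit: read the fundamental and overtone
frequencies off a synthesized or observed call.  For a pulse train with
inter-pulse interval dt the fundamental is 1/dt and the overtones sit at
integer multiples, so sub-bin frequency accuracy matters (a 7 s record at
2 kHz has only ~0.14 Hz raw resolution, not enough to separate 14.7 from
14.73 Hz).  Full-record spectra are Hann-windowed, zero-padded x4, and peak
frequencies are refined by 3-point parabolic interpolation on log power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .waveform import Waveform

__all__ = [
    "Spectrum",
    "HarmonicStructure",
    "LowProminenceWarning",
    "power_spectrum",
    "spectrogram",
    "estimate_fundamental",
    "find_harmonics",
    "fundamental_track",
]

#: a spectral peak is "prominent" when it stands this many dB above the
#: local median power
DEFAULT_PROMINENCE_DB = 6.0


class LowProminenceWarning(UserWarning):
    """The selected spectral peak barely stands above the local noise floor."""


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum on a uniform frequency grid.

    ``power`` is scaled so that ``power.sum()`` equals the energy of the
    windowed time-domain record (Parseval).
    """

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        p = np.asarray(self.power, dtype=np.float64)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and power must be matching 1-D arrays")
        if f[0] < 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must start >= 0 and increase strictly")
        if np.any(~np.isfinite(p)) or np.any(p < 0):
            raise ValueError("power must be finite and non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass(frozen=True)
class HarmonicStructure:
    """Fundamental plus located overtones of a harmonic comb."""

    fundamental: float
    overtones: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.overtones, dtype=np.float64)
        a = np.asarray(self.amplitudes, dtype=np.float64)
        if o.shape != a.shape:
            raise ValueError("overtones and amplitudes must match in length")
        if o.size > 1 and np.any(np.diff(o) <= 0):
            raise ValueError("overtones must be sorted ascending")
        object.__setattr__(self, "overtones", o)
        object.__setattr__(self, "amplitudes", a)

    @property
    def n_overtones(self) -> int:
        return self.overtones.size


def power_spectrum(w: Waveform, zero_pad_factor: int = 4) -> Spectrum:
    """Hann-windowed magnitude-squared spectrum of the full record.

    Frequency resolution is sample_rate / (zero_pad_factor * n_samples).
    """
    if len(w) < 16:
        raise ValueError("record too short (need >= 16 samples)")
    if zero_pad_factor < 1:
        raise ValueError("zero_pad_factor must be >= 1")
    x = w.samples * np.hanning(len(w))
    nfft = int(zero_pad_factor) * len(w)
    spec = np.fft.rfft(x, n=nfft)
    power = np.abs(spec) ** 2 / nfft
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / w.sample_rate)
    return Spectrum(freqs, power)


def spectrogram(
    w: Waveform, window_s: float = 1.0, overlap_fraction: float = 0.5
):
    """Hann-windowed short-time power spectra.

    Returns ``(frequencies, frame_times, sxx)`` with frame times at window
    centers, relative to the first sample.
    """
    nperseg = int(round(window_s * w.sample_rate))
    if nperseg < 16:
        raise ValueError("window too short (need >= 16 samples)")
    if nperseg > len(w):
        raise ValueError("window longer than the record")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    noverlap = int(round(overlap_fraction * nperseg))
    f, t, sxx = signal.spectrogram(
        w.samples,
        fs=w.sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=4 * nperseg,
        detrend=False,
        mode="psd",
    )
    return f, t, sxx


def _parabolic_refine(freqs: np.ndarray, power: np.ndarray, k: int):
    """Refine the peak at bin k by a parabola through log power; returns
    (frequency, power) at the interpolated vertex."""
    if k <= 0 or k >= power.size - 1:
        return float(freqs[k]), float(power[k])
    y = np.log(np.maximum(power[k - 1 : k + 2], 1e-300))
    denom = y[0] - 2.0 * y[1] + y[2]
    delta = 0.0 if denom == 0 else 0.5 * (y[0] - y[2]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    df = freqs[1] - freqs[0]
    peak_log = y[1] - 0.25 * (y[0] - y[2]) * delta
    return float(freqs[k] + delta * df), float(np.exp(peak_log))


def _local_median_db(s: Spectrum, k: int, halfwidth_hz: float) -> float:
    lo = np.searchsorted(s.frequencies, s.frequencies[k] - halfwidth_hz)
    hi = np.searchsorted(s.frequencies, s.frequencies[k] + halfwidth_hz)
    window = s.power[lo : max(hi, lo + 1)]
    return 10.0 * np.log10(np.maximum(np.median(window), 1e-300))


def estimate_fundamental(
    s: Spectrum,
    band: tuple[float, float] = (5.0, 25.0),
    prominence_db: float = DEFAULT_PROMINENCE_DB,
) -> float:
    """Frequency of the largest spectral peak inside ``band``, parabolic-refined.

    Emits :class:`LowProminenceWarning` when the winning peak is less than
    ``prominence_db`` above the local median power (e.g. on noise).
    Raises ValueError when the band holds no local maximum.
    """
    lo_hz, hi_hz = band
    if lo_hz < s.frequencies[0] or hi_hz > s.frequencies[-1] or lo_hz >= hi_hz:
        raise ValueError("band must lie within the spectrum range")
    lo = np.searchsorted(s.frequencies, lo_hz)
    hi = np.searchsorted(s.frequencies, hi_hz, side="right")
    peaks, _ = signal.find_peaks(s.power[lo:hi])
    if peaks.size == 0:
        raise ValueError("no local maximum inside the requested band")
    k = lo + peaks[int(np.argmax(s.power[lo + peaks]))]
    freq, peak_power = _parabolic_refine(s.frequencies, s.power, k)
    peak_db = 10.0 * np.log10(max(peak_power, 1e-300))
    if peak_db - _local_median_db(s, k, hi_hz - lo_hz) < prominence_db:
        warnings.warn(
            "fundamental peak has low prominence; estimate is unreliable",
            LowProminenceWarning,
            stacklevel=2,
        )
    return freq


def find_harmonics(
    s: Spectrum,
    fundamental: float,
    max_freq: float = 100.0,
    rel_tolerance: float = 0.25,
    prominence_db: float = DEFAULT_PROMINENCE_DB,
) -> HarmonicStructure:
    """Locate the overtone peaks of a comb with the given fundamental.

    For each harmonic number k >= 2 with k * fundamental <= max_freq, the
    most powerful prominent peak within rel_tolerance * fundamental of the
    ideal position is taken; harmonics with no such peak are simply absent
    from the output.
    """
    if fundamental <= 0:
        raise ValueError("fundamental must be positive")
    overtones, amplitudes = [], []
    k_max = int(np.floor(max_freq / fundamental))
    for k in range(2, k_max + 1):
        target = k * fundamental
        tol = rel_tolerance * fundamental
        lo = np.searchsorted(s.frequencies, target - tol)
        hi = np.searchsorted(s.frequencies, target + tol, side="right")
        if hi - lo < 3:
            continue
        peaks, _ = signal.find_peaks(s.power[lo:hi])
        best = None
        for p in lo + peaks:
            peak_db = 10.0 * np.log10(max(s.power[p], 1e-300))
            if peak_db - _local_median_db(s, p, fundamental) < prominence_db:
                continue
            if best is None or s.power[p] > s.power[best]:
                best = p
        if best is None:
            continue
        freq, pw = _parabolic_refine(s.frequencies, s.power, best)
        overtones.append(freq)
        amplitudes.append(pw)
    return HarmonicStructure(fundamental, np.asarray(overtones), np.asarray(amplitudes))


def fundamental_track(
    w: Waveform,
    window_s: float = 1.0,
    overlap_fraction: float = 0.75,
    band: tuple[float, float] = (3.0, 25.0),
):
    """Frame-wise fundamental estimate from the spectrogram.

    Returns ``(frame_times, f0_values)``; frames whose peak is off the grid
    edge fall back to the raw bin frequency.
    """
    f, t, sxx = spectrogram(w, window_s, overlap_fraction)
    lo = np.searchsorted(f, band[0])
    hi = np.searchsorted(f, band[1], side="right")
    f0 = np.empty(t.size)
    for j in range(t.size):
        col = sxx[lo:hi, j]
        k = lo + int(np.argmax(col))
        f0[j], _ = _parabolic_refine(f, sxx[:, j], k)
    return t, f0
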