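"""Pulse-train call synthesis: repeat the wavelet at an inter-pulse schedule.

A harmonic call is built by overlap-adding copies of the pulse wavelet whose
maximum-amplitude samples sit at scheduled onset times.  For a constant
inter-pulse interval dt the result is a harmonic comb with fundamental 1/dt
and overtones at integer multiples; a time-varying schedule shifts the
fundamental track as the reciprocal of the local interval while preserving
the harmonic spacing frame by frame.  A raised-cosine (Tukey) taper is
applied to the whole train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows

from .waveform import Waveform
from .wavelet import PulseShape, rescale_duration, sample_pulse

__all__ = [
    "IntervalSchedule",
    "PulseTrainSpec",
    "intervals_from_f0_track",
    "constant_schedule",
    "cosine_taper",
    "synthesize_train",
]


@dataclass(frozen=True)
class IntervalSchedule:
    """Sequence of pulse onset times implied by inter-pulse intervals.

    ``onsets[0] == 0``; ``onsets[k+1] - onsets[k] == intervals[k]``.
    """

    onsets: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.atleast_1d(np.asarray(self.onsets, dtype=np.float64))
        if onsets.size < 1 or not np.all(np.isfinite(onsets)):
            raise ValueError("schedule needs at least one finite onset")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("onset times must be strictly increasing")
        object.__setattr__(self, "onsets", onsets)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.onsets)

    def __len__(self) -> int:
        return self.onsets.size


def constant_schedule(interval: float, total_duration: float) -> IntervalSchedule:
    """Onsets at 0, dt, 2dt, ... covering [0, total_duration)."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    n = int(np.ceil(total_duration / interval))
    return IntervalSchedule(np.arange(max(n, 1)) * interval)


def intervals_from_f0_track(f0_values, total_duration: float) -> IntervalSchedule:
    """Build a schedule whose local interval is 1/f0 at each onset time.

    ``f0_values`` is a fundamental-frequency track (Hz) sampled uniformly
    over [0, total_duration]; intermediate values are linearly interpolated.
    """
    f0 = np.atleast_1d(np.asarray(f0_values, dtype=np.float64))
    if f0.size < 1 or np.any(~np.isfinite(f0)) or np.any(f0 <= 0):
        raise ValueError("f0 track must be positive and finite")
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    track_t = (
        np.linspace(0.0, total_duration, f0.size) if f0.size > 1 else np.array([0.0])
    )
    onsets = []
    t = 0.0
    while t < total_duration:
        onsets.append(t)
        t += 1.0 / float(np.interp(t, track_t, f0))
    return IntervalSchedule(np.asarray(onsets))


def cosine_taper(n_samples: int, taper_fraction: float) -> np.ndarray:
    """Symmetric raised-cosine envelope, maximum 1.

    ``taper_fraction`` is the total fraction of the record under the two
    cosine ramps (taper_fraction/2 at each end): 0 gives a boxcar, 1 the
    full Hann window.  This is the Tukey window.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not 0.0 <= taper_fraction <= 1.0:
        raise ValueError("taper_fraction must lie in [0, 1]")
    return windows.tukey(n_samples, alpha=taper_fraction, sym=True)


@dataclass(frozen=True)
class PulseTrainSpec:
    """Everything needed to synthesize one pulse-train call.

    Attributes
    ----------
    shape : PulseShape
        Wavelet parameters.
    pulse_duration : float
        Effective wavelet duration in seconds after rescaling (the B-call
        model uses 0.068 s).
    schedule : IntervalSchedule
        Pulse onset times.
    total_duration : float
        Record length in seconds.
    sample_rate : float
        Hz; must exceed twice the highest overtone of interest.
    taper_fraction : float
        Whole-train Tukey taper extent in [0, 1].
    """

    shape: PulseShape = field(default_factory=PulseShape)
    pulse_duration: float = 0.068
    schedule: IntervalSchedule = field(
        default_factory=lambda: constant_schedule(1.0 / 14.73, 7.0)
    )
    total_duration: float = 7.0
    sample_rate: float = 2000.0
    taper_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")


def b_call_spec(
    f0: float = 14.73,
    total_duration: float = 7.0,
    sample_rate: float = 2000.0,
    pulse_duration: float | None = None,
    taper_fraction: float = 0.1,
    shape: PulseShape | None = None,
) -> PulseTrainSpec:
    """Convenience constructor for a constant-fundamental B-call model.

    With the defaults this is the canonical model call: wavelets of duration
    1/f0 (0.0679 s at 14.73 Hz) repeated every 1/f0 seconds for 7 s at 2 kHz.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    interval = 1.0 / f0
    return PulseTrainSpec(
        shape=shape or PulseShape(),
        pulse_duration=interval if pulse_duration is None else pulse_duration,
        schedule=constant_schedule(interval, total_duration),
        total_duration=total_duration,
        sample_rate=sample_rate,
        taper_fraction=taper_fraction,
    )


def synthesize_train(spec: PulseTrainSpec) -> Waveform:
    """Overlap-add peak-normalized wavelets at the scheduled onsets.

    The maximum-amplitude sample of each wavelet lands at its onset time
    (nearest-sample placement), so the comb fundamental equals the
    reciprocal of the time spacing of the wavelet maxima.  Wavelets may
    overlap; the tails are summed.  A whole-train Tukey taper finishes the
    call.
    """
    n = int(round(spec.total_duration * spec.sample_rate))
    if n < 2:
        raise ValueError("total_duration too short for this sample rate")
    onsets = spec.schedule.onsets
    if onsets[-1] >= spec.total_duration:
        raise ValueError("schedule extends beyond total_duration")

    base = sample_pulse(spec.shape, spec.sample_rate)
    pulse = rescale_duration(base, spec.pulse_duration)
    if len(pulse) < 4:
        raise ValueError("sample_rate too low to represent the pulse")
    kernel = pulse.samples / np.max(np.abs(pulse.samples))
    peak = int(np.argmax(np.abs(kernel)))

    out = np.zeros(n)
    idx = np.rint(onsets * spec.sample_rate).astype(int) - peak
    for start in idx:
        lo, hi = max(start, 0), min(start + kernel.size, n)
        if hi > lo:
            out[lo:hi] += kernel[lo - start : hi - start]
    out *= cosine_taper(n, spec.taper_fraction)
    return Waveform(out, spec.sample_rate)
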