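"""Uniformly sampled time series — the currency passed between all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Waveform:
    """A mono, uniformly sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence, dimensionless (arbitrary units).
    sample_rate : float
        Sampling rate in Hz, > 0.
    start_time : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not (np.isfinite(self.sample_rate) and self.sample_rate > 0):
            raise ValueError("sample_rate must be positive and finite")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n_samples / sample_rate)."""
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``start_time``."""
        return self.start_time + np.arange(self.samples.size) / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        """Copy of this waveform with the sample array replaced."""
        return Waveform(samples, self.sample_rate, self.start_time)
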