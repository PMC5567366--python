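"""Resonance-style sinusoid models of the B call, for comparison with the
pulse-train mechanism.

Two readings of the variable-phase sine model are provided:

* ``literal-chirp`` — a single amplitude-interpolated sinusoid whose
  frequency ramps from F0 to F1 through an accumulated phase term; sample i
  has amplitude A0 + i (A1 - A0)/(N - 1) and phase
  P + (2 pi / R) * sum_{j=0}^{i} [ j (F1 - F0)/N + F0 ].
* ``harmonic-stack`` — the fundamental and first overtone as two such
  components centred at F0 and F1, each sweeping linearly downward across
  +/- sweep_halfwidth (B calls step down in frequency), with amplitudes
  chosen to keep the summed signal within +/- 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .waveform import Waveform

__all__ = [
    "SinusoidModelParams",
    "synthesize_sp",
    "synthesize_harmonic_stack",
    "synthesize_sinusoid",
]


@dataclass(frozen=True)
class SinusoidModelParams:
    """Parameters of the variable-phase sinusoid model.

    Attributes
    ----------
    sample_rate : float
        R, in Hz.
    n_samples : int
        N, the number of data points (the literal chirp emits N - 1 samples).
    f0, f1 : float
        Hz. In literal-chirp mode the sweep start/end frequencies; in
        harmonic-stack mode the centre frequencies of the fundamental and
        first overtone (14.73 and 29.5 Hz for the modelled call).
    a0, a1 : float
        Amplitude coefficients. Defaults keep the stacked signal within
        +/- 1.5 (|a0| + |a1| = 1.5).
    phase : float
        P, initial phase in radians (0 in the modelled call).
    mode : str
        "literal-chirp" or "harmonic-stack".
    sweep_halfwidth : float
        Hz; each stack component sweeps centre + h down to centre - h.
    """

    sample_rate: float = 2000.0
    n_samples: int = 14000
    f0: float = 14.73
    f1: float = 29.5
    a0: float = 0.9
    a1: float = 0.6
    phase: float = 0.0
    mode: Literal["literal-chirp", "harmonic-stack"] = "harmonic-stack"
    sweep_halfwidth: float = 0.42

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.f0 <= 0 or self.f1 <= 0:
            raise ValueError("frequencies must be positive")
        if self.mode not in ("literal-chirp", "harmonic-stack"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sweep_halfwidth < 0:
            raise ValueError("sweep_halfwidth must be >= 0")


def _chirp(
    n: int, rate: float, f_start: float, f_end: float, phase: float,
    n_div: int | None = None,
) -> np.ndarray:
    """Unit-amplitude accumulated-phase chirp over n output samples.

    The per-sample instantaneous frequency is
    f_start + i (f_end - f_start)/n_div; the phase is its cumulative sum
    scaled by 2 pi / R, matching the model's variable phase term (whose
    frequency increment divisor is the full point count N even though only
    N - 1 samples are emitted).
    """
    i = np.arange(n)
    inst_freq = i * (f_end - f_start) / (n_div or n) + f_start
    return np.sin(phase + (2.0 * np.pi / rate) * np.cumsum(inst_freq))


def synthesize_sp(params: SinusoidModelParams) -> Waveform:
    """Literal-chirp mode: one sinusoid sweeping F0 -> F1.

    Emits N - 1 samples with a linear amplitude ramp from A0 to A1.
    """
    n_out = params.n_samples - 1
    i = np.arange(n_out)
    amp = params.a0 + i * (params.a1 - params.a0) / (params.n_samples - 1)
    samples = amp * _chirp(
        n_out, params.sample_rate, params.f0, params.f1, params.phase,
        n_div=params.n_samples,
    )
    return Waveform(samples, params.sample_rate)


def synthesize_harmonic_stack(params: SinusoidModelParams) -> Waveform:
    """Harmonic-stack mode: fundamental + first overtone, each sweeping
    linearly from centre + sweep_halfwidth down to centre - sweep_halfwidth.
    """
    n = params.n_samples
    h = params.sweep_halfwidth
    fund = params.a0 * _chirp(
        n, params.sample_rate, params.f0 + h, params.f0 - h, params.phase
    )
    over = params.a1 * _chirp(
        n, params.sample_rate, params.f1 + h, params.f1 - h, params.phase
    )
    return Waveform(fund + over, params.sample_rate)


def synthesize_sinusoid(params: SinusoidModelParams) -> Waveform:
    """Dispatch on ``params.mode``."""
    if params.mode == "literal-chirp":
        return synthesize_sp(params)
    return synthesize_harmonic_stack(params)
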