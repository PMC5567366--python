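"""The short-duration pressure pulse at the heart of the pulsed-air call model.

A single pneumatic pulse is modelled as the time derivative of a piecewise
rational function::

    q(t) = 1 / [(t - a)^2 + eps_pre]              for t < a
    q(t) = scale_post / [(t - a)^2 + eps_post]    for t > a
    P(t) = dq/dt

``a`` sets the time of the pulse peak; with the canonical constants
(eps_pre = 0.01, eps_post = 0.1, scale_post = 10) the two branches agree at
t = a (both equal 100), so q is continuous and P is a biphasic wavelet: a
sharp positive swing before t = a followed by a slower negative recovery.
The asymmetry (fast attack, slow decay) mimics the restriction-and-release
airflow of a respiratory valve snapping shut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import Waveform

__all__ = [
    "PulseShape",
    "eval_q",
    "eval_pulse",
    "sample_pulse",
    "effective_duration",
    "rescale_duration",
]

#: fraction of the peak magnitude defining the pulse's effective support
SUPPORT_THRESHOLD = 0.01


@dataclass(frozen=True)
class PulseShape:
    """Parameters of the pulse wavelet.

    Attributes
    ----------
    a : float
        Peak-time constant in seconds; sets the time length of the pulse.
    eps_pre : float
        Pre-peak denominator offset (dimensionless).
    eps_post : float
        Post-peak denominator offset.
    scale_post : float
        Post-peak numerator scale.
    """

    a: float = 0.3
    eps_pre: float = 0.01
    eps_post: float = 0.1
    scale_post: float = 10.0

    def __post_init__(self) -> None:
        for name in ("a", "eps_pre", "eps_post", "scale_post"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @property
    def is_continuous(self) -> bool:
        """True when both branches of q meet at t = a (1/eps_pre == scale_post/eps_post)."""
        return np.isclose(1.0 / self.eps_pre, self.scale_post / self.eps_post)


def _check_t(t):
    t = np.asarray(t, dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    return t


def eval_q(t, shape: PulseShape = PulseShape()):
    """Evaluate the piecewise rational q(t).

    At t = a the pre-peak branch value 1/eps_pre is returned, which for the
    canonical constants equals the shared two-sided limit (100).
    """
    t = _check_t(t)
    u = t - shape.a
    pre = 1.0 / (u * u + shape.eps_pre)
    post = shape.scale_post / (u * u + shape.eps_post)
    out = np.where(u <= 0, pre, post)
    return out.item() if out.ndim == 0 else out


def eval_pulse(t, shape: PulseShape = PulseShape()):
    """Evaluate the pulse P(t) = dq/dt via the analytic derivative.

    ``-2 (t-a) / [(t-a)^2 + eps_pre]^2`` before the peak and
    ``-2 scale_post (t-a) / [(t-a)^2 + eps_post]^2`` after; P(a) = 0 since
    both one-sided derivatives vanish (the factor (t - a) is zero).
    """
    t = _check_t(t)
    u = t - shape.a
    d_pre = u * u + shape.eps_pre
    d_post = u * u + shape.eps_post
    pre = -2.0 * u / (d_pre * d_pre)
    post = -2.0 * shape.scale_post * u / (d_post * d_post)
    out = np.where(u <= 0, pre, post)
    return out.item() if out.ndim == 0 else out


def sample_pulse(
    shape: PulseShape = PulseShape(),
    sample_rate: float = 2000.0,
    support: tuple[float, float] | None = None,
) -> Waveform:
    """Sample P(t) on a uniform grid over ``support`` (default [0, 2a]).

    The support must lie within t > 0 and be non-degenerate.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if support is None:
        support = (0.0, 2.0 * shape.a)
    t0, t1 = float(support[0]), float(support[1])
    if t0 < 0 or t1 < 0:
        raise ValueError("support must lie within t >= 0")
    if t1 <= t0:
        raise ValueError("support must be a non-empty interval")
    n = int(round((t1 - t0) * sample_rate))
    if n < 2:
        raise ValueError("support too short for this sample rate")
    t = t0 + np.arange(n) / sample_rate
    return Waveform(eval_pulse(t, shape), sample_rate, start_time=t0)


def effective_duration(pulse: Waveform, threshold: float = SUPPORT_THRESHOLD) -> float:
    """Width of the interval where |P| >= ``threshold`` x max |P|, in seconds."""
    mag = np.abs(pulse.samples)
    above = np.flatnonzero(mag >= threshold * mag.max())
    return (above[-1] - above[0] + 1) / pulse.sample_rate


def rescale_duration(pulse: Waveform, target_duration: float) -> Waveform:
    """Compress (or stretch) the time axis so the effective support of the
    pulse equals ``target_duration``.

    The amplitude shape is preserved up to band-limited resampling and the
    output keeps the input sample rate.  This reconciles the canonical
    a = 0.3 wavelet (~0.6 s support) with the 0.068 s wavelet used in the
    B-call model: a shorter valve-open time, identical pulse shape.
    """
    if not (np.isfinite(target_duration) and target_duration > 0):
        raise ValueError("target_duration must be positive")
    current = effective_duration(pulse)
    factor = target_duration / current
    n_out = int(round(len(pulse) * factor))
    if n_out < 4:
        raise ValueError("target_duration yields fewer than 4 output samples")
    # linear interpolation on the compressed time grid; the pulse is smooth
    # and heavily oversampled at its native support, so interpolation error
    # is negligible relative to the 1 % support threshold
    x_in = np.arange(len(pulse))
    x_out = np.linspace(0.0, len(pulse) - 1, n_out)
    samples = np.interp(x_out, x_in, pulse.samples)
    return Waveform(samples, pulse.sample_rate, start_time=pulse.start_time)
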