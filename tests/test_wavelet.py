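"""The pulse wavelet: closed-form values, derivative oracle, support rescaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsecall import PulseShape, eval_pulse, eval_q, rescale_duration, sample_pulse
from pulsecall.wavelet import effective_duration


class TestEvalQ:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.3, 100.0),  # both branches meet at t = a
            (0.2, 1.0 / ((-0.1) ** 2 + 0.01)),  # pre-peak branch
            (0.6, 10.0 / (0.3**2 + 0.1)),  # post-peak branch
        ],
    )
    def test_default_constants_by_substitution(self, t, expected):
        assert eval_q(t) == pytest.approx(expected, rel=1e-12)

    def test_continuity_at_peak(self):
        deltas = np.array([1e-2, 1e-3, 1e-4, 1e-5])
        gaps = np.abs(eval_q(0.3 - deltas) - eval_q(0.3 + deltas))
        assert np.all(np.diff(gaps) < 0)  # gap shrinks as delta -> 0
        assert gaps[-1] < 1e-5

    def test_rejects_non_finite_t(self):
        with pytest.raises(ValueError):
            eval_q(np.nan)
        with pytest.raises(ValueError):
            eval_q(np.inf)

    def test_positive_everywhere(self):
        t = np.linspace(-2.0, 2.0, 4001)
        assert np.all(eval_q(t) > 0)


class TestEvalPulse:
    def test_zero_at_peak_time(self):
        assert eval_pulse(0.3) == 0.0

    def test_extrema_match_calculus(self):
        # d2q/dt2 = 0 at t = a -/+ sqrt(eps/3) on each branch
        shape = PulseShape()
        t_max = shape.a - np.sqrt(shape.eps_pre / 3.0)
        t_min = shape.a + np.sqrt(shape.eps_post / 3.0)
        assert t_max == pytest.approx(0.24226, abs=1e-5)
        assert t_min == pytest.approx(0.48257, abs=1e-5)
        # confirm by dense grid search
        t = np.linspace(1e-4, 1.0, 400001)
        p = eval_pulse(t)
        assert t[np.argmax(p)] == pytest.approx(t_max, abs=1e-5)
        assert t[np.argmin(p)] == pytest.approx(t_min, abs=1e-5)
        assert p.max() == pytest.approx(649.519, abs=0.01)
        assert p.min() == pytest.approx(-205.396, abs=0.01)

    def test_sign_pattern_around_peak(self):
        t_pre = np.linspace(1e-6, 0.3 - 1e-6, 1001)
        t_post = np.linspace(0.3 + 1e-6, 5.0, 1001)
        assert np.all(eval_pulse(t_pre) > 0)
        assert np.all(eval_pulse(t_post) < 0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=1e-3, max_value=2.0))
    def test_matches_finite_difference_of_q(self, t):
        """Analytic derivative vs central difference of q, away from t = a."""
        h = 1e-5
        if abs(t - 0.3) <= 2 * h:
            return
        fd = (eval_q(t + h) - eval_q(t - h)) / (2 * h)
        assert eval_pulse(t) == pytest.approx(fd, rel=1e-3)


class TestSamplePulse:
    def test_default_support_is_biphasic(self):
        w = sample_pulse(sample_rate=2000.0, support=(0.0, 0.6))
        assert len(w) == 1200
        peak, trough = np.argmax(w.samples), np.argmin(w.samples)
        assert w.samples[peak] > 0 > w.samples[trough]
        assert peak < trough  # positive swing precedes the negative one

    def test_effective_support_under_one_second(self):
        w = sample_pulse()
        assert effective_duration(w) < 1.0

    def test_rejects_degenerate_or_negative_support(self):
        with pytest.raises(ValueError):
            sample_pulse(support=(0.3, 0.3))
        with pytest.raises(ValueError):
            sample_pulse(support=(-0.1, 0.6))

    def test_finite_difference_of_sampled_q_matches_sampled_p(self):
        sr = 20000.0
        w = sample_pulse(sample_rate=sr)
        q = eval_q(w.times)
        fd = np.gradient(q, 1.0 / sr)
        # away from the peak cusp region the agreement is tight
        mask = np.abs(w.times - 0.3) > 0.02
        assert np.allclose(fd[mask], w.samples[mask], rtol=5e-3)


class TestRescaleDuration:
    def test_identity_when_target_equals_current(self):
        w = sample_pulse()
        out = rescale_duration(w, effective_duration(w))
        assert out.sample_rate == w.sample_rate
        assert np.allclose(out.samples, w.samples, rtol=1e-6, atol=1e-9)

    def test_hits_printed_b_call_wavelet_duration(self):
        w = sample_pulse()
        out = rescale_duration(w, 0.068)
        assert effective_duration(out) == pytest.approx(0.068, abs=1.0 / w.sample_rate)

    def test_halving_duration_doubles_peak_frequency(self):
        from pulsecall import power_spectrum
        from pulsecall.waveform import Waveform

        w = sample_pulse(sample_rate=8000.0)
        half = rescale_duration(w, effective_duration(w) / 2.0)
        # embed each pulse in silence so the FFT sees an isolated transient
        def peak_freq(p):
            padded = Waveform(np.pad(p.samples, (0, 80000 - len(p))), p.sample_rate)
            s = power_spectrum(padded)
            return s.frequencies[np.argmax(s.power)]

        assert peak_freq(half) == pytest.approx(2.0 * peak_freq(w), rel=0.05)

    def test_rejects_tiny_targets(self):
        w = sample_pulse()
        with pytest.raises(ValueError):
            rescale_duration(w, 1e-4)

    def test_energy_normalized_pulse_independent_of_sample_rate(self):
        energies = []
        for sr in (2000.0, 8000.0):
            w = sample_pulse(sample_rate=sr)
            x = w.samples / np.max(np.abs(w.samples))
            energies.append(np.sum(x * x) / sr)
        assert energies[0] == pytest.approx(energies[1], rel=1e-3)


class TestPulseShapeValidation:
    @pytest.mark.parametrize("kwargs", [dict(a=0.0), dict(eps_pre=-1.0), dict(scale_post=0.0)])
    def test_rejects_non_positive_parameters(self, kwargs):
        with pytest.raises(ValueError):
            PulseShape(**kwargs)

    def test_default_constants_are_continuous(self):
        assert PulseShape().is_continuous
        assert not PulseShape(scale_post=5.0).is_continuous
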