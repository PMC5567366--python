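"""Band-pass, normalized cross-correlation, and grid-search model fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from oracles import brute_xcorr

from pulsecall import (
    SinusoidModelParams,
    Waveform,
    b_call_spec,
    bandpass,
    compare_models,
    fit_pulse_train,
    synthesize_harmonic_stack,
    synthesize_train,
    xcorr_r,
)


def tone(freq, duration=7.0, sr=2000.0):
    t = np.arange(int(duration * sr)) / sr
    return Waveform(np.sin(2 * np.pi * freq * t), sr)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        w = tone(14.73)
        out = bandpass(w, 10.0, 100.0)
        assert np.max(np.abs(out.samples)) == pytest.approx(1.0, rel=0.05)
        assert len(out) == len(w)

    def test_out_of_band_tone_attenuated(self):
        w = tone(500.0)
        out = bandpass(w, 10.0, 100.0)
        attenuation_db = 20 * np.log10(np.max(np.abs(out.samples[2000:-2000])))
        assert attenuation_db < -40.0

    def test_dc_removed(self):
        w = Waveform(np.ones(14000), 2000.0)
        out = bandpass(w, 10.0, 100.0)
        assert np.max(np.abs(out.samples)) < 1e-6

    def test_rejects_invalid_band(self):
        w = tone(20.0)
        with pytest.raises(ValueError):
            bandpass(w, 100.0, 10.0)
        with pytest.raises(ValueError):
            bandpass(w, 10.0, 1500.0)  # above Nyquist


class TestXcorrR:
    def test_self_correlation_is_one_at_zero_lag(self, fig4_waveform):
        r, lag = xcorr_r(fig4_waveform, fig4_waveform)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert lag == 0.0

    def test_polarity_flip_gives_minus_one(self, fig4_waveform):
        r, _ = xcorr_r(fig4_waveform, fig4_waveform.with_samples(-fig4_waveform.samples))
        assert r == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("seed,nx,ny", [(0, 4000, 4000), (1, 4000, 3000), (2, 2500, 4000)])
    def test_matches_brute_force_oracle(self, seed, nx, ny):
        """Fast FFT + cumulative-sum path vs the O(n^2) direct sum."""
        rng = np.random.default_rng(seed)
        x = Waveform(rng.standard_normal(nx), 2000.0)
        y = Waveform(rng.standard_normal(ny), 2000.0)
        r_fast, lag_fast = xcorr_r(x, y, max_lag=0.3)
        r_ref, lag_ref = brute_xcorr(x, y, max_lag=0.3)
        assert r_fast == pytest.approx(r_ref, abs=1e-9)
        assert lag_fast == pytest.approx(lag_ref, abs=1e-12)

    def test_model_cross_family_correlation_matches_oracle(self):
        w_train = synthesize_train(b_call_spec(total_duration=2.0))
        w_sine = synthesize_harmonic_stack(
            SinusoidModelParams(n_samples=len(w_train))
        )
        r_fast, _ = xcorr_r(w_train, w_sine, max_lag=0.25)
        r_ref, _ = brute_xcorr(w_train, w_sine, max_lag=0.25)
        assert r_fast == pytest.approx(r_ref, abs=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(min_value=0.01, max_value=100.0),
           offset=st.floats(min_value=-10.0, max_value=10.0))
    def test_invariant_to_scale_and_offset(self, scale, offset):
        rng = np.random.default_rng(11)
        x = Waveform(rng.standard_normal(4000), 2000.0)
        y = Waveform(rng.standard_normal(4000), 2000.0)
        r0, lag0 = xcorr_r(x, y, max_lag=0.2)
        y2 = y.with_samples(scale * y.samples + offset)
        r1, lag1 = xcorr_r(x, y2, max_lag=0.2)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert lag1 == lag0

    def test_known_lag_recovered(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(6000)
        x = Waveform(base, 2000.0)
        shift = 150  # 0.075 s
        y = Waveform(np.concatenate([np.zeros(shift), base]), 2000.0)
        r, lag = xcorr_r(x, y, max_lag=0.2)
        assert r > 0.999
        assert lag == pytest.approx(shift / 2000.0, abs=1e-12)

    def test_rejects_sample_rate_mismatch(self):
        with pytest.raises(ValueError):
            xcorr_r(tone(20.0, sr=2000.0), tone(20.0, sr=8000.0))


class TestFitPulseTrain:
    def test_recovers_self_generated_train(self):
        truth_dt = 1.0 / 14.73
        observed = synthesize_train(b_call_spec())
        grid = np.array([0.05, 0.06, truth_dt, 0.08, 0.09])
        result = fit_pulse_train(observed, grid)
        assert float(result.params.schedule.intervals[0]) == pytest.approx(truth_dt)
        assert result.r > 0.999

    def test_octave_candidate_rejected(self):
        """A grid containing 2 x dt must not win over dt (subharmonic comb)."""
        truth_dt = 1.0 / 14.73
        observed = synthesize_train(b_call_spec())
        grid = np.array([truth_dt, 2.0 * truth_dt])
        result = fit_pulse_train(observed, grid)
        assert float(result.params.schedule.intervals[0]) == pytest.approx(truth_dt)

    def test_sinusoid_input_never_fits_perfectly(self):
        observed = synthesize_harmonic_stack(SinusoidModelParams(n_samples=14000))
        result = fit_pulse_train(observed, np.linspace(0.06, 0.08, 11))
        assert result.r < 1.0

    def test_rejects_short_records_and_empty_grids(self):
        short = synthesize_train(b_call_spec(total_duration=1.0))
        with pytest.raises(ValueError):
            fit_pulse_train(short, [0.068])
        with pytest.raises(ValueError):
            fit_pulse_train(synthesize_train(b_call_spec()), [])


class TestCompareModels:
    def test_single_candidate_table(self, fig4_waveform, fig4_spec):
        table = compare_models(fig4_waveform, [fig4_spec])
        assert len(table) == 1
        assert table[0].model_kind == "pulse-train"
        assert table[0].r > 0.999

    def test_ranking_sorted_descending(self, fig4_waveform, fig4_spec):
        sine = SinusoidModelParams(n_samples=len(fig4_waveform))
        table = compare_models(fig4_waveform, [sine, fig4_spec])
        assert [fr.model_kind for fr in table] == ["pulse-train", "sinusoid"]
        assert table[0].r >= table[1].r
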