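# Methods

## The pulse wavelet

A single pneumatic pulse is the time derivative P(t) = dq/dt of

    q(t) = 1 / [(t − a)² + 0.01]     t < a
    q(t) = 10 / [(t − a)² + 0.1]     t > a

with `a` (seconds) the peak-time constant. With these constants both
branches equal 100 at t = a, so q is continuous; P is evaluated from the
analytic derivative on each branch and defined as 0 at t = a, where both
one-sided derivatives vanish. The shape is a fast positive swing peaking at
t = a − √(0.01/3) ≈ a − 0.058 followed by a slower negative recovery with
its trough at t = a + √(0.1/3) ≈ a + 0.183 — the restriction-and-release
airflow signature of a valve snapping shut. A central finite-difference
oracle of q lives in the tests; the library itself always uses the closed
form.

"Pulse duration" is operationalized as the width of the interval where
|P| ≥ 1 % of max |P|. The canonical a = 0.3 pulse sampled on [0, 0.6 s]
has an effective duration of 0.6 s; the B-call model uses a 0.068 s
wavelet, obtained by compressing the time axis (`rescale_duration`) so the
effective support hits the target while the amplitude shape and sample
rate are preserved. Rescaling uses linear interpolation on the index grid;
the pulse is smooth and heavily oversampled at its native support, so
interpolation error is far below the 1 % support threshold.

## Train synthesis

A call is the overlap-add of peak-normalized wavelets whose
maximum-amplitude samples sit at scheduled onset times; the comb
fundamental is therefore keyed to the time spacing of the wavelet maxima.
Onsets are real-valued and each wavelet is placed at the nearest sample
(placement error ≤ 0.25 ms at the 2 kHz default, ~0.4 % of the 0.068 s
interval). Pulse count is always derived from the record duration and the
schedule, never user-specified. The whole train is shaped by a Tukey
window: `cosine_taper(n, f)` ramps over f/2 of the record at each end, so
f = 0 is a boxcar and f = 1 the full Hann window; the default extent is
f = 0.1, a conventional light taper (the model literature specifies a
cosine taper but not its extent).

The canonical call (`b_call_spec()`) uses a fundamental of exactly
14.73 Hz, i.e. an inter-pulse interval of 1/14.73 ≈ 0.06789 s, with the
wavelet duration equal to the interval (contiguous pulses). A printed
spacing of "0.068 s" is the 2-decimal rounding of this interval; using
0.068 s literally would put the 6th harmonic at 88.24 Hz rather than the
88.4 Hz the comb law k·f₀ predicts, so the frequency is taken as primary.

Time-varying schedules are built from a fundamental-frequency track:
onsets are placed iteratively with the local interval equal to 1/f₀ at the
onset time (linear interpolation between track points). The frame-wise
spectrogram fundamental then follows the reciprocal local interval while
the harmonic spacing is preserved — the mechanism by which a whale could
retune a call mid-stream.

## The sinusoid comparison model

The resonance-style alternative is a sine with linearly interpolated
amplitude and an accumulated variable phase: sample i (of N − 1) has
amplitude A₀ + i(A₁ − A₀)/(N − 1) and phase
P + (2π/R)·Σ_{j≤i}[j(F₁ − F₀)/N + F₀], giving an instantaneous frequency
ramping from F₀ toward F₁. Two modes are provided because the printed
formulation (a sweep from the fundamental to the first overtone,
14.73 → 29.5 Hz) is hard to reconcile with the stated "slight frequency
sweep" of ±0.42 Hz:

* **literal-chirp** — the formula exactly as written;
* **harmonic-stack** (default) — fundamental and first overtone as two
  accumulated-phase components centred at F₀ and F₁, each sweeping
  linearly from centre + 0.42 Hz down to centre − 0.42 Hz (downswept, the
  B-call convention), amplitudes A₀ = 0.9, A₁ = 0.6 so the sum stays
  within ±1.5.

Both are implemented and labelled rather than silently choosing one.

## Spectral analysis

Full-record spectra are Hann-windowed and zero-padded ×4; power is scaled
so the one-sided spectrum sums to the windowed-signal energy (Parseval).
A 7 s record at 2 kHz has 0.143 Hz raw resolution — not enough to separate
14.7 from 14.73 Hz — so every reported peak frequency is refined by a
3-point parabola through log power, giving millihertz-level accuracy on
clean combs. Peaks are "prominent" when they stand ≥ 6 dB above the local
median power (default; the threshold is an argument everywhere). On pure
noise the winning spectral peak typically sits ~9 dB above the local
median, so the default threshold treats it as a peak; raising the
threshold to 12 dB flags such estimates with `LowProminenceWarning` while
genuine comb lines (≈ 40 dB above median) still pass. Overtone search
accepts the strongest prominent peak within 0.25·f₀ of each ideal
harmonic; missing harmonics are simply absent from the result.
Spectrograms use Hann windows with frame times at window centers; all
spectra are single-sided on a linear frequency grid.

## Correlation fitting

`xcorr_r` computes the normalized cross-correlation — both overlapping
segments mean-removed and energy-normalized per lag — for every integer
lag within ±0.5 s (default), and returns the signed value of largest
magnitude with its lag. The implementation uses one FFT cross-correlation
plus cumulative-sum sliding statistics, making the per-lag normalization
exact at O(n log n); an O(n²) direct-sum oracle in the tests confirms
agreement to 10⁻⁹. Lags leaving less than 1 s of overlap are not searched.

Fitting is forward modelling by grid search: one candidate train per
(interval, duration) grid point, both signals band-passed to 10–100 Hz
(the call's energy band) with a 4th-order zero-phase Butterworth, scored
by r. Ties break toward the smaller interval, then the smaller duration.
Because a train at 2Δt contains every comb frequency of the train at Δt,
grid candidates are filtered to those whose fundamental 1/Δt lies within
25 % of the observed record's low-band (< 25 Hz) spectral peak before the
argmax, which resolves the octave ambiguity.

The correlation objective is extremely narrow in Δt: a 0.5 % interval
error dephases a 7 s train by half a period near its end, so a blind
coarse grid can straddle the basin without touching it.
`auto_fit_pulse_train` therefore seeds the grid from the spectral
fundamental estimate (accurate to ~0.1 % even at 5 dB SNR), searches ±1 %
in 0.1 % steps, then zooms to ±0.2 % in 0.02 % steps. `compare_models`
correlates an arbitrary list of pulse-train and sinusoid specs against a
record and ranks them by r.

## Synthetic scenes

The hydrophone recordings behind the model are not publicly deposited, so
recovery experiments run on synthetic scenes with known truth:

* **multipath** — delayed, scaled, polarity-flipped copies of the call;
  defaults two echoes at 0.03 and 0.04 s with gains 0.4 and 0.3 and
  polarities −1, +1, emulating the observed secondary arrivals between
  fundamental peaks (seafloor/reef reflections). Gains and polarities are
  config-exposed; the true values at any real site are unknown.
* **noise** — white Gaussian noise zero-phase band-passed to 5–400 Hz
  (flat in band), scaled so the in-band signal-to-noise power ratio equals
  the requested dB value. This is the simplest testable stand-in for
  wind/wave ambient noise, which is broadband and reaches below 10 Hz; it
  has no swell spectrum, no shipping tones, no impulsive interference.

Scenes are bit-exactly reproducible from their integer seed. Passing
recovery tests on these scenes shows the estimator chain is correct and
noise-robust under the modelled degradations; it does not certify
performance against real ocean noise, moving sources, or propagation
physics, none of which are modelled.

## Problem sizes and test conditions

Synthesis and analysis default to 7 s records at 2 kHz (14 000 samples),
the regime of the modelled call; 8 kHz operation is supported. Recovery
experiments use 20 seeded scenes per condition with the ground-truth
fundamental jittered ±3 % around 14.73 Hz, SNRs of 20/10/5 dB with echoes
on, and model-selection runs at 10 dB with noise only. Across those
conditions the median recovered-interval error stays well under 1 % at
20/10 dB and under 5 % at 5 dB, and correlation-based ranking identifies
the generating mechanism in ≥ 18 of 20 seeds per direction.

## Known limitations

* No physiology: the wavelet is a phenomenological pulse shape; nothing
  here models the U-fold, laryngeal sac, or airflow mechanics.
* No propagation physics: multipath is a tapped-delay line, not ray or
  mode theory (which the shallow-water geometry would invalidate anyway).
* The fitter assumes a constant inter-pulse interval; time-varying
  schedules can be synthesized and tracked spectrally but not yet fitted.
* Printed correlation values against the original recordings cannot be
  reproduced without those recordings; the toolkit instead validates the
  machinery on synthetic scenes with known truth.
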