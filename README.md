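# pulsecall

Synthesis and analysis toolkit for the **pulsed-air model of blue whale
B calls**.

Northeastern Pacific blue whales produce B calls — tonal harmonic signals
10–20 s long with a fundamental near 14–16 Hz and overtones at integer
multiples. The traditional explanation is Helmholtz-style resonance of
air-filled organs, which ties call frequency to body size. The pulse-train
hypothesis instead treats the call as a rapid series of short pneumatic
pulses from the opening and closing of laryngeal respiratory valves: the
fundamental is then simply the reciprocal of the inter-pulse interval
Δt, and the animal can retune it by changing the pulse timing.

`pulsecall` implements that model end to end, for bioacousticians who want
to synthesize, analyze, and compare harmonic pulse-train calls:

* **wavelet** — the single pressure pulse P(t) = dq/dt with the piecewise
  rational q(t) = 1/[(t−a)² + 0.01] for t < a and 10/[(t−a)² + 0.1] for
  t > a, where `a` sets the pulse length; plus time-axis rescaling to any
  target pulse duration.
* **train** — overlap-add synthesis of calls from a constant or
  time-varying inter-pulse schedule, with a raised-cosine taper. For
  constant Δt the spectrum is a harmonic comb at k/Δt.
* **sinusoid** — the competing resonance-style model: an
  amplitude-interpolated sine with accumulated variable phase
  (literal-chirp mode) and a two-component harmonic stack whose tones sweep
  ±0.42 Hz (harmonic-stack mode).
* **spectral** — zero-padded Hann spectra, spectrograms, sub-bin
  fundamental estimation by parabolic peak interpolation, overtone
  extraction, frame-wise frequency tracks.
* **fit** — normalized cross-correlation r maximized over lag, and
  forward-model grid fitting of the inter-pulse interval to an observed
  record.
* **scene** — synthetic hydrophone scenes: ground-truth call + delayed,
  scaled, polarity-flipped multipath echoes (0.03/0.04 s defaults) +
  band-limited ambient noise at a prescribed SNR, fully seeded.

## Worked example

Synthesize the canonical model call — the 0.068 s wavelet repeated at the
14.73 Hz fundamental's reciprocal interval for 7 s at 2 kHz — and read its
harmonic structure back:

```sh
$ pulsecall synth-train --f0 14.73 --duration 7 --sr 2000 --out bcall.wav
$ pulsecall analyze bcall.wav --band 5,100
  component  frequency_hz
fundamental     14.729966
 overtone_1     29.459885
 overtone_2     44.189881
 overtone_3     58.919778
 overtone_4     73.649779
 overtone_5     88.379682
```

The fundamental comes out at 14.73 Hz with five overtones at its integer
multiples below 100 Hz — the harmonic comb the pulse mechanism predicts
from a 0.0679 s inter-pulse spacing alone. Ranking the two call models
against this record by normalized cross-correlation:

```sh
$ pulsecall compare bcall.wav
[
  {"model_kind": "pulse-train", "r": 1.0,  "lag_s": 0.0},
  {"model_kind": "sinusoid",    "r": 0.41, "lag_s": 0.4615}
]
```

The pulse-train fit matches its own generating mechanism exactly (r = 1)
while the two-tone sinusoid stack, sharing the same fundamental, cannot
reproduce the full comb (r ≈ 0.41).

The same workflow runs from Python:

```python
from pulsecall import (b_call_spec, synthesize_train, power_spectrum,
                       estimate_fundamental, find_harmonics)

call = synthesize_train(b_call_spec(f0=14.73))
spectrum = power_spectrum(call)
f0 = estimate_fundamental(spectrum, band=(5, 25))      # 14.73 Hz
harmonics = find_harmonics(spectrum, f0, max_freq=100) # 5 overtones
```

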