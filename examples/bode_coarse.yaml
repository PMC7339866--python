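# Coarse frequency-response profile of the entrainable loop.
model:
  preset: exogenous
freqs_hz: [5, 10, 15, 20, 25, 30, 40, 50]
input_mean: 50.0
input_amplitude: 10.0
settle_ms: 2000.0
measure_ms: 2000.0
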