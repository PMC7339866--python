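# Reduced-resolution oscillation map over the coupling grid.
model:
  preset: map_template
c12_values: [0.0, 2.0, 4.0]
c21_values: [0.0, 16.0, 32.0]
duration_ms: 3000.0
measure_ms: 1500.0
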