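# Target-variation scenario: self-tuning vs fixed-gain controllers.
scenario: target_variation
controllers:
  - {label: self_tuning, mode: adaptive_arv, tau_theta_ms: 100.0, sigma: 0.00875}
  - {label: prop_low, mode: proportional, theta: 3.0}
  - {label: prop_high, mode: proportional, theta: 40.0}
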