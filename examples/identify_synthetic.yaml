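# Recover a known GPe activation (scale 1.29) and self-coupling 0.35 from
# synthetic steady-state rate pairs with 5% multiplicative noise.
activation: {m: 400.0, b: 75.0, scale: 1.29}
c22_true: 0.35
n: 50
noise: 0.05
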