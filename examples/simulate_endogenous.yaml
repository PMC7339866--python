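# Endogenous beta oscillations with the self-tuning controller switched on at
# 200 ms and a cortical input step 27 -> 42 at 750 ms (reduced duration).
model:
  preset: endogenous
u1:
  kind: constant
  level: [27.0, 42.0]
  switch_times_ms: [750.0]
controller:
  mode: adaptive_abs
  tau_theta_ms: 75.0
  sigma: 0.19
  t_on_ms: 200.0
integrator:
  dt: 0.1
  duration: 1500.0
perturb: 5.0
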