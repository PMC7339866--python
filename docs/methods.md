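# Methods

## The model

The package simulates a two-population firing-rate abstraction of the
reciprocally coupled STN (excitatory) and GPe (inhibitory) populations of the
basal ganglia:

```
tau1 x1'(t) = -x1(t) + S1( c11 x1(t-d11) - c12 x2(t-d12) + b1 u1(t) + mu(t) )
tau2 x2'(t) = -x2(t) + S2( c21 x1(t-d21) - c22 x2(t-d22) - b2 u2(t) )
```

`x1, x2` are population firing rates (pulses/s); `u1, u2` cortical and
striatal drives weighted by `b1, b2 >= 0`; `c_ij >= 0` synaptic coupling
strengths whose signs in the equations encode the excitatory/inhibitory
identity of the presynaptic population; `d_ij >= 0` transmission delays (ms);
`mu(t)` the stimulation input to the STN.  The activations are sigmoids with
unit maximal slope,

```
S(x) = a M B / (B + exp(-4 x / M) (M - B)),
```

so `S(0) = aB`, `sup S = aM`, and the maximal slope equals the output scale
`a` (default 1).  Default constants: `M1 = 300`, `B1 = 17`, `M2 = 400`,
`B2 = 75` pulses/s; `tau1 = 6`, `tau2 = 14` ms; `d12 = d21 = 6`, `d22 = 4` ms;
`c11 = d11 = 0` (no STN self-excitation in any standard parameterization).

Two standard operating regimes are shipped as presets:

* `LoopParams.endogenous()` — `c12 = 3, c21 = 10, c22 = 0.9, b1 = 5,
  b2 = 139.4`.  Strong mutual coupling destabilizes the resting equilibrium;
  the loop sustains a limit cycle at 20.5 Hz (beta band) under constant
  cortical drive 27.
* `LoopParams.exogenous()` — `c12 = 1.12, c21 = 19, c22 = 0.9, b1 = 2.42,
  b2 = 15.1`.  The loop is stable and entrainable: any periodic cortical
  input produces a periodic steady state at the same frequency, which is what
  makes nonlinear frequency-response (Bode) profiles well defined.
* `LoopParams.map_template()` — `c22 = 4, b1 = 8, b2 = 139.4` with `c12, c21`
  swept over [0, 4] x [0, 32] for oscillation maps.

Unprinted inputs.  The striatal level is not part of the printed
parameterizations; the default `u2 = 2` is the striatal rate of the lineage
firing-rate model of this loop and puts the GPe at a plausible operating point
with the `b2` weights above.  Endogenous runs default to cortical drive
`u1 = 27`.  Both are ordinary config fields; absolute amplitudes of any
specific published trace are not reproducible without the exact input levels
and initial histories, and no result here depends on them.

## Integration

A DDE's state at time `t` is the history segment `x_t(s) = x(t+s)`,
`s in [-d_max, 0]`; the integrator keeps the whole trajectory on a uniform
grid and resolves delayed references from it.  The scheme is explicit
fixed-step RK4; delayed terms at the half-step stage times are linearly
interpolated between grid samples (they are exact at whole steps).  Every
delay must be an integer multiple of `dt` — enforced, never rounded — which
removes any interpolation ambiguity at the exact lags.  The interpolation of
lagged stage values limits the observed convergence order to ~2 (ratio ≈ 4
under step halving, verified in the tests); at the default `dt = 0.1` ms
(>= 40 steps per delay, >= 330 steps per beta period) discretization error is
far below any quantity interpreted here.  The integrator refuses to continue
past a non-finite state and reports the failure time.

Initial histories default to the constant equilibrium — simulations start at
rest.  In the unstable regime an exact equilibrium start stays on the fixed
point forever (equilibrium invariance is a test), so oscillation studies kick
the STN history by a small `perturb` offset (1–5 pulses/s); the limit-cycle
frequency and amplitude do not depend on the kick.

Equilibria are computed by nested 1-D bracketing: for given `x1` the GPe
equation `x2 = S2(c21 x1 - c22 x2 - b2 u2)` is strictly decreasing in `x2`
and has a unique root; substituting it into the STN equation leaves a strictly
decreasing scalar problem (for `c11 = 0`), so the loop equilibrium is unique
and found to residual < 1e-10.  This is robust at strong coupling, where
plain fixed-point iteration is not a contraction.

## Controllers

All firing-rate controllers act on the deviation from the resting equilibrium
at the reference (t = 0) input level, `mu(t) = -theta(t) (x1(t) - x1_eq)`,
entering inside the S1 argument (negative feedback).  Modes:

* `proportional` — fixed `theta`.
* `adaptive_abs` — `tau_theta theta' = |x1 - x1_eq| - sigma theta`.
* `adaptive_beta` — the drive is the beta biomarker: peak-to-peak of the
  causally band-passed (Butterworth order 5, 15–30 Hz) STN deviation over the
  trailing 500 ms window (zero until the window first fills).  Filter state is
  carried across steps; the windowed peak-to-peak is refreshed at a 1 ms
  cadence and held in between — the gain dynamics are orders of magnitude
  slower.
* `adaptive_arv` — the plant-facing positive-feedback mode (below).

The leak `-sigma theta` is the σ-modification of adaptive control: it bounds
the gain and lets it dissipate when pathological activity is absent, at the
cost of a residual steady-state deviation proportional to `sigma`.  The gain
ODE is linear, so with the drive held over a step it has an exact solution;
the update uses that integrating-factor step,

```
theta <- theta exp(-sigma dt / tau) + drive (1 - exp(-sigma dt / tau)) / sigma
```

(limit `theta + drive dt / tau` for `sigma -> 0`), clamped at zero.  This is
exact for piecewise-constant drive — the closed-form decay/relaxation checks
in the tests hold to 1e-6 over tens of thousands of steps, which a plain Euler
update (relative rate error `sigma dt / 2 tau`) would not achieve.  The
stimulation value is held over each integration step (zero-order hold); gain
state advances once per step.

Choosing the drive matters for how the gain hovers.  With the beta-biomarker
drive on an endogenously oscillating loop, successful suppression extinguishes
the drive entirely, so the gain enters a slow relaxation cycle (decay — burst —
re-adaptation) and "the adapted gain" is only defined on average.  The
`adaptive_abs` drive never quite vanishes and settles to a smooth hover near
the minimal effective gain; the robustness-contrast experiment (below) uses it
for that reason.

## Characterization experiments

Oscillation maps.  For each `(c12, c21)` cell the loop is integrated 5 s
from a nudged equilibrium; the last 2 s of each rate are band-passed
(Butterworth order 5, 16–24 Hz, zero-phase — offline analysis may be acausal)
and the peak-to-peak recorded, then normalized to [0, 1] per population panel.
All cells integrate as one vectorized batch.  Empirical note: the normalized
amplitude peaks at intermediate coupling — at the strongest couplings the
limit cycle shifts partly out of the 16–24 Hz analysis band — so the
high-coupling corner of the grid is bright but not the panel maximum.

Bode profiles.  The entrainable loop is driven by `u1 = mean + A sin(2 pi
f t)` for a list of frequencies (all integrated as one batch, 3 s settle +
2 s measurement by default); the per-frequency amplitude ratio is half the
steady-state peak-to-peak of the output over the input amplitude `A`.  Cells
whose dominant output frequency is not the input frequency (within one FFT bin
plus 2% leakage slack) are flagged as non-entrained rather than silently
reported.  For small `A` the ratios match the magnitude of the linearized
transfer function

```
H1(iw) = s1 b1 / (D1 + s1 c12 e^{-iw d12} s2 c21 e^{-iw d21} / D2),
D1 = 1 + iw tau1 - s1 c11 e^{-iw d11},  D2 = 1 + iw tau2 + s2 c22 e^{-iw d22},
```

with `s_i` the activation slopes at the operating point (within 10% at
`A = 0.5`, verified in the tests).  Default means for the two-level resonance
comparison are 40 and 50 with amplitude 10: 50/10 is the standard exogenous
drive, and the companion level must stay inside the entrainable regime (by
mean 60 the loop oscillates endogenously), so the weaker level sits below.
The self-tuning controller (`sigma = 0.1`, `tau_theta = 50` ms) flattens the
beta resonance while leaving the 5 Hz and 50 Hz responses essentially
untouched — the beta-selective drive delivers no stimulation without beta
content.

Dominant frequency is the largest non-DC rFFT peak of the post-transient
(default 1 s discarded) signal; flat signals return `None`, never 0.  With 4 s
of analysis window the bin width is 0.25 Hz.

## Identification

From (STN rate, GPe steady-state rate) pairs, the GPe activation is estimated
in the decoupled regime `c22 = 0` by the two-stage procedure — linear fit on
the central 50% of the drive range for the overall scale `a`, unit-slope
sigmoid fit to the rescaled data — followed by a joint `(a, M, B)`
least-squares refinement seeded at the two-stage values.  The refinement is
needed for unbiased recovery: a straight line fitted across a sigmoid's
central half systematically underestimates its maximal slope, so the bare
two-stage estimate of `a` is biased low by several percent even on noiseless
data.  With the activation fixed, the self-coupling `c22` is estimated by
grid search (default 0 : 0.01 : 0.9/l2, ties toward the smaller value) over
the normalized squared error between measured steady states and the fixed
point of `x = S2(u + c22 x)`, solved by damped iteration (damping 0.5,
residual < 1e-12), which converges under the contraction condition
`c22 l2 < 1` — the same condition, with `l2` the activation's maximal slope,
that stabilizability of the closed loop requires.

The synthetic pair generator draws drives uniformly over the activation's
dynamic range (inflection ± M) and applies multiplicative Gaussian noise of
stated relative s.d.; noiseless recovery is exact (scale 1.29, `c22 = 0.35`
to grid precision), and 5% noise with n = 50 recovers `c22` within 10%.

## Surrogate plant and scenarios

The conductance-based network that motivates the plant module is out of scope
here; the surrogate reproduces only its closed-loop observable: a beta-ARV
biomarker (uV) that decreases monotonically and saturates as stimulation
amplitude rises.  Ingredients: `ARV = background(t) * supp(I_eff) + noise`
with a logistic suppression curve `supp` (half-point 0.4 mA, width 0.15 mA,
floor 5% of background), effective current `I_eff = I * Z(0)/Z(t)` for a
current-controlled stimulus under impedance `Z(t)`, a 500 ms first-order
response lag, and additive Gaussian sample noise (s.d. 5% of the high
background).  Background levels are 0.35 uV (high beta) and 0.08 uV (low).
These scales were fixed once so that the gains required to hold the scenario
targets span roughly 5–30 — comparable to the fixed-gain ranges a clinician
would sweep — and so the `sigma = 0.00875` leak keeps the steady tracking
offset under ~25% of target; they are study conditions, not tuning knobs.

The controller runs at the biomarker epoch cadence (100 ms; plant integrated
at 1 ms): `I_DBS = theta * ARV` (positive feedback — more stimulation means
less biomarker) with the σ-modification law driven by the half-wave rectified
*normalized* error `max((ARV - target)/target, 0)`; defaults `tau_theta =
100` ms, `sigma = 0.00875`.  Normalizing the drive makes the controller's
equilibrium offset scale-free across the 0.05–0.2 uV targets, and matches the
normalized error that the MSE measure integrates.

Three 130 s scenarios exercise adaptation: stepping the suppression target
(10, 0.2, 0.05, 0.15, 10 uV at 0/10/40/70/100 s) under high background;
switching background beta low/high under a fixed 0.1 uV target; ramping the
impedance linearly from 0.5 kOhm (constant until 30 s) to 2.5 kOhm at 130 s.
Performance is summarized by `MSE = (1/T) \int e^2 dt` (reported as % of the
stimulation-off MSE of the same scenario and seed) and mean power
`PC = (1/T) \int Z I^2 dt` in uW (kOhm · mA² = mW).  Under all three
scenarios the self-tuning controller tracks each attainable target, beats a
low fixed gain on error and a high fixed gain on power, raises its gain
monotonically through the impedance ramp, and stays silent while the target
exceeds the background.

What the surrogate does not capture: spiking dynamics, DBS pulse shape and
frequency, antidromic/orthodromic activation, LFP biophysics, and the
absolute MSE/power numbers of any particular detailed network — passing the
scenario tests shows the *orderings* and adaptation behavior, not clinical
effect sizes.

## Numerical choices and edge cases

* `dt = 0.1` ms default (all delays are integer multiples); transient discard
  1 s for steady-state analyses; map/Bode measurement windows 2 s.
* Firing rates are asserted to stay in `[0, a_i M_i]` after every simulation
  (the sigmoid plus leak makes this region invariant; a violation indicates a
  mis-set step).
* Overflow-safe sigmoid evaluation (exponent clipped at ±700).
* ARV filter: Chebyshev type I, order 4, 21–29 Hz; the passband ripple is a
  free design constant fixed at 0.5 dB and recorded in `FilterSpec` so results
  are reproducible.
* Performance integrals use the trapezoidal rule on the sampling grid.
* `theta_star_bound` is undefined at `c22 = 1` (raises); the gain clamp at 0
  guards the discrete update against drive-free undershoot.
* Degenerate identification inputs (constant response, all-equal drives,
  non-positive pre-fit slope, empty grids) raise with explicit messages.

## Known limitations

* The robustness contrast against a matched fixed gain is a meaningful
  comparison only when the operating-point change *raises* the required
  equilibrium gain; input steps that push the loop deeper into activation
  saturation can lower it, in which case the matched proportional controller
  is not handicapped and no ordering is claimed.
* Zero-phase filtering in offline analyses is acausal by construction; all
  in-the-loop filtering is causal.
* Batched parameter sweeps share one integration grid and settle time; a cell
  far slower to settle than its batch would need a longer run (the entrainment
  flags catch this for Bode profiles).
* The simulation loop is pure NumPy; a 5 s run at `dt = 0.1` ms takes a few
  seconds, and large grids amortize this through vectorized batching rather
  than parallelism.
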