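"""Two-population delayed firing-rate model of the STN-GPe loop.

The subthalamic nucleus (STN, excitatory) and external globus pallidus (GPe,
inhibitory) are each represented by their population firing rate (pulses/s)::

    tau1 x1'(t) = -x1(t) + S1(c11 x1(t-d11) - c12 x2(t-d12) + b1 u1(t) + mu(t))
    tau2 x2'(t) = -x2(t) + S2(c21 x1(t-d21) - c22 x2(t-d22) - b2 u2(t))

``u1`` and ``u2`` are cortical and striatal drives, ``c_ij >= 0`` synaptic
coupling strengths with signs fixed by the excitatory/inhibitory identity of the
presynaptic population, ``d_ij`` axonal/synaptic transmission delays (ms), and
``mu(t)`` the stimulation (DBS) feedback acting on the STN input.  The
activation functions are sigmoids with unit maximal slope,

    S(x) = a * M * B / (B + exp(-4 x / M) (M - B)),

so ``S(0) = a*B`` and ``S`` saturates at ``a*M`` (the optional output scale
``a`` appears when activations are identified from data).

Strong mutual coupling destabilizes the loop into sustained *endogenous*
oscillations, which fall in the beta band (13-30 Hz) for the parameterizations
used here.  With weak coupling the loop is stable and entrainable, and
oscillations are *exogenous*: the loop amplifies periodic cortical input at the
input's own frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .dde_core import (
    ConfigurationError,
    IntegratorConfig,
    integrate_dde,
)

__all__ = [
    "ActivationParams",
    "activation",
    "activation_slope",
    "activation_max_slope",
    "shift_activation",
    "LoopParams",
    "InputSignal",
    "Equilibrium",
    "find_equilibrium",
    "Trajectory",
    "simulate",
    "DEFAULT_TRANSIENT_MS",
]

#: Transient discarded by default in steady-state analyses (ms).
DEFAULT_TRANSIENT_MS = 1000.0


# ---------------------------------------------------------------------------
# Activation functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivationParams:
    """Sigmoid activation constants.

    Parameters
    ----------
    m : float
        Maximum firing rate (pulses/s).
    b : float
        Baseline rate at zero input (pulses/s); ``0 < b < m``.
    scale : float
        Output scale ``a`` (dimensionless, default 1).  The activation maps
        into ``(0, a*m)`` and its maximal slope equals ``a``.
    """

    m: float
    b: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.b < self.m):
            raise ValueError(f"require 0 < b < m, got b={self.b}, m={self.m}")
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def max_rate(self) -> float:
        """Saturation level ``a*m`` (pulses/s)."""
        return self.scale * self.m


#: STN activation constants (M1 = 300, B1 = 17 pulses/s).
STN_ACTIVATION = ActivationParams(m=300.0, b=17.0)
#: GPe activation constants (M2 = 400, B2 = 75 pulses/s).
GPE_ACTIVATION = ActivationParams(m=400.0, b=75.0)


def activation(p: ActivationParams, x):
    """Evaluate ``a*M*B / (B + exp(-4x/M)(M-B))``, overflow-safe.

    Output lies strictly in ``(0, a*M)`` and is strictly increasing in ``x``.
    """
    z = np.clip(-4.0 * np.asarray(x, dtype=float) / p.m, -700.0, 700.0)
    out = p.scale * p.m * p.b / (p.b + np.exp(z) * (p.m - p.b))
    if np.ndim(x) == 0:
        return float(out)
    return out


def activation_slope(p: ActivationParams, x):
    """Analytic derivative of :func:`activation` at ``x``."""
    z = np.clip(-4.0 * np.asarray(x, dtype=float) / p.m, -700.0, 700.0)
    e = np.exp(z) * (p.m - p.b)
    out = 4.0 * p.scale * p.b * e / (p.b + e) ** 2
    if np.ndim(x) == 0:
        return float(out)
    return out


def activation_max_slope(p: ActivationParams, n_grid: int = 200_001) -> float:
    """Supremum of the activation derivative, by finite differences on a fine grid.

    The sigmoid is logistic with rate ``4/M`` and output span ``a*M``, so the
    analytic supremum is exactly ``a``; the numeric route keeps this routine
    honest for any monotone activation plugged in later.
    """
    # centre the grid on the inflection point, span well past the slope decay
    x_inf = 0.25 * p.m * math.log((p.m - p.b) / p.b)
    xs = np.linspace(x_inf - 2.0 * p.m, x_inf + 2.0 * p.m, n_grid)
    ys = activation(p, xs)
    return float(np.max(np.diff(ys) / np.diff(xs)))


def shift_activation(p: ActivationParams, x0: float) -> Callable:
    """Shifted activation ``f(y) = S(y + x0) - S(x0)`` with ``f(0) = 0``.

    This is the change of variables used to move an equilibrium to the origin;
    monotonicity and the maximal slope are unaffected.
    """
    s0 = activation(p, x0)

    def shifted(y):
        return activation(p, np.asarray(y, dtype=float) + x0) - s0

    return shifted


# ---------------------------------------------------------------------------
# Loop parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopParams:
    """All constants of the delayed firing-rate loop.

    Times in ms, couplings dimensionless and >= 0.  ``c11``/``d11`` (STN
    self-coupling) default to 0: every parameterization used in practice omits
    them.  Coupling fields accept arrays for vectorized parameter sweeps.
    """

    c12: float | np.ndarray
    c21: float | np.ndarray
    c22: float | np.ndarray
    b1: float
    b2: float
    c11: float | np.ndarray = 0.0
    tau1: float = 6.0
    tau2: float = 14.0
    d11: float = 0.0
    d12: float = 6.0
    d21: float = 6.0
    d22: float = 4.0
    s1: ActivationParams = STN_ACTIVATION
    s2: ActivationParams = GPE_ACTIVATION

    def __post_init__(self) -> None:
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise ValueError("time constants must be positive")
        for name in ("c11", "c12", "c21", "c22", "b1", "b2"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"coupling {name} must be non-negative")
        for name in ("d11", "d12", "d21", "d22"):
            if getattr(self, name) < 0:
                raise ValueError(f"delay {name} must be non-negative")

    @property
    def delays(self) -> tuple[float, float, float, float]:
        return (self.d11, self.d12, self.d21, self.d22)

    @property
    def batch_size(self) -> int:
        return int(
            np.broadcast(
                np.asarray(self.c11),
                np.asarray(self.c12),
                np.asarray(self.c21),
                np.asarray(self.c22),
            ).size
        )

    # Standard parameterizations -------------------------------------------

    @classmethod
    def endogenous(cls) -> "LoopParams":
        """Strong-coupling regime with sustained endogenous beta oscillations."""
        return cls(c12=3.0, c21=10.0, c22=0.9, b1=5.0, b2=139.4)

    @classmethod
    def exogenous(cls) -> "LoopParams":
        """Weak-coupling, entrainable regime (exogenous oscillations)."""
        return cls(c12=1.12, c21=19.0, c22=0.9, b1=2.42, b2=15.1)

    @classmethod
    def map_template(cls, c12=0.0, c21=0.0) -> "LoopParams":
        """Template for coupling-space oscillation maps (c12 in 0-4, c21 in 0-32)."""
        return cls(c12=c12, c21=c21, c22=4.0, b1=8.0, b2=139.4)


# ---------------------------------------------------------------------------
# Input signals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputSignal:
    """Cortical or striatal drive as a function of time.

    Kinds
    -----
    constant
        ``level`` throughout (or per-segment levels with ``switch_times_ms``).
    sinusoid
        ``level + amplitude * sin(2 pi f t)``; ``level`` and ``amplitude`` may
        be per-segment sequences switching at ``switch_times_ms``.
    sampled
        Linear interpolation of ``samples`` on a uniform grid ``sample_dt_ms``.

    ``level``, ``amplitude`` and ``frequency_hz`` may be arrays to drive a
    batch of simulations with different inputs.
    """

    kind: str = "constant"
    level: float | Sequence | np.ndarray = 0.0
    amplitude: float | Sequence | np.ndarray = 0.0
    frequency_hz: float | np.ndarray = 0.0
    switch_times_ms: tuple = ()
    samples: np.ndarray | None = None
    sample_dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid", "sampled"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if self.kind == "sampled" and self.samples is None:
            raise ValueError("sampled input requires samples")

    def _segment(self, t: float) -> int:
        return int(np.searchsorted(np.asarray(self.switch_times_ms), t, side="right"))

    def _pick(self, values, t: float):
        if self.switch_times_ms and isinstance(values, (list, tuple)):
            return values[min(self._segment(t), len(values) - 1)]
        return values

    def value(self, t: float):
        """Drive at time ``t`` (ms); scalar or array matching the batch."""
        if self.kind == "sampled":
            grid = np.arange(len(self.samples)) * self.sample_dt_ms
            if t < -1e-9 or t > grid[-1] + 1e-9:
                raise ValueError(f"sampled input not defined at t = {t} ms")
            return float(np.interp(t, grid, self.samples))
        level = np.asarray(self._pick(self.level, t), dtype=float)
        if self.kind == "constant":
            return level if level.ndim else float(level)
        amp = np.asarray(self._pick(self.amplitude, t), dtype=float)
        out = level + amp * np.sin(2.0e-3 * np.pi * np.asarray(self.frequency_hz) * t)
        return out if out.ndim else float(out)

    __call__ = value

    def reference_level(self):
        """Constant level used for equilibrium computation (level at t = 0)."""
        level = self._pick(self.level, 0.0)
        return np.asarray(level, dtype=float) if np.ndim(level) else float(level)

    @classmethod
    def constant(cls, level) -> "InputSignal":
        return cls(kind="constant", level=level)

    @classmethod
    def step(cls, levels: Sequence[float], switch_times_ms: Sequence[float]) -> "InputSignal":
        return cls(kind="constant", level=tuple(levels),
                   switch_times_ms=tuple(switch_times_ms))

    @classmethod
    def sinusoid(cls, mean, amplitude, frequency_hz,
                 switch_times_ms: Sequence[float] = ()) -> "InputSignal":
        if isinstance(mean, (list, tuple)):
            mean = tuple(mean)
        if isinstance(amplitude, (list, tuple)):
            amplitude = tuple(amplitude)
        return cls(kind="sinusoid", level=mean, amplitude=amplitude,
                   frequency_hz=frequency_hz, switch_times_ms=tuple(switch_times_ms))


#: Default striatal drive level: 2 pulses/s, the customary striatal rate for
#: this family of basal-ganglia loop models; with the standard b2 weights it
#: puts the GPe at a plausible operating point.  An explicit, overridable choice.
DEFAULT_U2 = 2.0


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Equilibrium:
    """Fixed point of the loop under constant drive, with its residual norm."""

    x1: float
    x2: float
    residual: float


def _gpe_fixed_point(p: LoopParams, c21: float, c22: float, x1: float, u2: float) -> float:
    """Solve x2 = S2(c21*x1 - c22*x2 - b2*u2) by bracketing (unique: RHS is
    strictly decreasing in x2)."""
    from scipy.optimize import brentq

    def g(x2: float) -> float:
        return activation(p.s2, c21 * x1 - c22 * x2 - p.b2 * u2) - x2

    hi = p.s2.max_rate
    if c22 == 0.0:
        return activation(p.s2, c21 * x1 - p.b2 * u2)
    return brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16)


def find_equilibrium(
    p: LoopParams,
    u1: float = 0.0,
    u2: float = DEFAULT_U2,
    tol: float = 1e-10,
) -> Equilibrium:
    """Equilibrium of the loop for constant inputs (delays are irrelevant).

    Solves the coupled fixed-point equations by nested 1-D bracketing: for each
    trial ``x1`` the unique GPe fixed point is found (the GPe equation is
    strictly decreasing in ``x2``), then ``x1`` is bracketed on the STN
    equation.  With ``c11 = 0`` the reduced STN equation is strictly decreasing,
    so the equilibrium is unique.
    """
    from scipy.optimize import brentq

    c11 = float(np.asarray(p.c11).reshape(-1)[0]) if np.ndim(p.c11) else float(p.c11)
    if p.batch_size != 1:
        raise ValueError("find_equilibrium expects scalar couplings; loop over cells")
    c12, c21, c22 = float(np.asarray(p.c12)), float(np.asarray(p.c21)), float(np.asarray(p.c22))

    def h(x1: float) -> float:
        x2 = _gpe_fixed_point(p, c21, c22, x1, u2)
        return activation(p.s1, c11 * x1 - c12 * x2 + p.b1 * u1) - x1

    hi = p.s1.max_rate
    x1 = brentq(h, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    x2 = _gpe_fixed_point(p, c21, c22, x1, u2)
    r1 = activation(p.s1, c11 * x1 - c12 * x2 + p.b1 * u1) - x1
    r2 = activation(p.s2, c21 * x1 - c22 * x2 - p.b2 * u2) - x2
    residual = float(np.hypot(r1, r2))
    if residual > tol:
        raise RuntimeError(
            f"equilibrium solve did not reach tolerance {tol}; last residual {residual:.3e}"
        )
    return Equilibrium(x1=float(x1), x2=float(x2), residual=residual)


def _equilibria_batch(p: LoopParams, u1_ref, u2_ref) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell equilibria for (possibly) array-valued couplings and inputs."""
    n = p.batch_size
    c11 = np.broadcast_to(np.asarray(p.c11, dtype=float), (n,)).ravel()
    c12 = np.broadcast_to(np.asarray(p.c12, dtype=float), (n,)).ravel()
    c21 = np.broadcast_to(np.asarray(p.c21, dtype=float), (n,)).ravel()
    c22 = np.broadcast_to(np.asarray(p.c22, dtype=float), (n,)).ravel()
    u1a = np.broadcast_to(np.asarray(u1_ref, dtype=float), (n,)).ravel()
    u2a = np.broadcast_to(np.asarray(u2_ref, dtype=float), (n,)).ravel()
    x1 = np.empty(n)
    x2 = np.empty(n)
    for i in range(n):
        cell = replace(p, c11=c11[i], c12=c12[i], c21=c21[i], c22=c22[i])
        eq = find_equilibrium(cell, u1=u1a[i], u2=u2a[i])
        x1[i], x2[i] = eq.x1, eq.x2
    return x1, x2


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-stamped record of a simulation.

    Arrays have shape ``(n_times, n_batch)``; single runs have ``n_batch = 1``.
    ``theta`` and ``mu`` are zero when no controller is attached.
    """

    t_ms: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    theta: np.ndarray
    mu: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    dt_ms: float
    x1_eq: np.ndarray | None = None
    x2_eq: np.ndarray | None = None

    @property
    def fs_hz(self) -> float:
        """Sampling rate of the trajectory grid in Hz."""
        return 1000.0 / self.dt_ms

    @property
    def n_batch(self) -> int:
        return self.x1.shape[1]

    def column(self, name: str, cell: int = 0) -> np.ndarray:
        return getattr(self, name)[:, cell]

    def to_dataframe(self, cell: int | None = None):
        """Single-run (or one-cell) frame with columns t_ms, x1, x2, theta, mu, u1, u2."""
        import pandas as pd

        if cell is None:
            if self.n_batch != 1:
                raise ValueError(
                    "trajectory holds a batch; pass cell=... or use to_long_dataframe()"
                )
            cell = 0
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "x1": self.x1[:, cell],
                "x2": self.x2[:, cell],
                "theta": self.theta[:, cell],
                "mu": self.mu[:, cell],
                "u1": self.u1[:, cell],
                "u2": self.u2[:, cell],
            }
        )

    def to_long_dataframe(self):
        import pandas as pd

        frames = []
        for c in range(self.n_batch):
            f = self.to_dataframe(cell=c)
            f.insert(0, "cell", c)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        """Delimited-text export, one header line, full float precision."""
        df = self.to_dataframe() if self.n_batch == 1 else self.to_long_dataframe()
        df.to_csv(path, index=False, float_format="%.17g")


def _fast_input(u: InputSignal):
    """Specialized evaluator for the common input kinds (hot path)."""
    if u.kind == "constant" and not u.switch_times_ms:
        v = np.asarray(u.level, dtype=float)
        v = float(v) if v.ndim == 0 else v
        return lambda t: v
    if u.kind == "sinusoid" and not u.switch_times_ms:
        mean = np.asarray(u.level, dtype=float)
        amp = np.asarray(u.amplitude, dtype=float)
        omega = 2.0e-3 * np.pi * np.asarray(u.frequency_hz, dtype=float)
        return lambda t: mean + amp * np.sin(omega * t)
    return u.value


def simulate(
    p: LoopParams,
    u1: InputSignal,
    u2: InputSignal | None = None,
    controller=None,
    cfg: IntegratorConfig | None = None,
    history=None,
    perturb: float = 0.0,
    check_bounds: bool = True,
) -> Trajectory:
    """Integrate the loop, optionally in closed loop with a DBS controller.

    The controller (see :mod:`stngpe.controllers`) acts on the deviation of the
    STN rate from its equilibrium at the reference (t = 0) input levels,
    ``mu(t) = -theta(t) * (x1(t) - x1_eq)``, entering inside the S1 argument.
    Its gain state is advanced once per integration step and the resulting
    stimulation held over the following step.

    The initial history defaults to the constant equilibrium (simulations start
    at rest); ``perturb`` adds an offset (pulses/s) to the STN history, which
    is how runs in the unstable regime are kicked off the fixed point.  Firing
    rates are asserted to stay inside ``[0, a_i * M_i]``.
    """
    from .controllers import make_runtime  # local import, avoids cycle

    if u2 is None:
        u2 = InputSignal.constant(DEFAULT_U2)
    if cfg is None:
        cfg = IntegratorConfig(dt=0.1, duration=1000.0)

    n_model = p.batch_size
    n_input = int(np.broadcast(
        np.asarray(u1.reference_level()), np.asarray(u1.frequency_hz),
        np.asarray(u2.reference_level()),
    ).size)
    n = max(n_model, n_input)
    if controller is not None:
        n = max(n, int(np.asarray(getattr(controller, "sigma", 0.0)).size),
                int(np.asarray(getattr(controller, "theta", 0.0)).size))

    c11 = np.broadcast_to(np.asarray(p.c11, dtype=float), (n,))
    c12 = np.broadcast_to(np.asarray(p.c12, dtype=float), (n,))
    c21 = np.broadcast_to(np.asarray(p.c21, dtype=float), (n,))
    c22 = np.broadcast_to(np.asarray(p.c22, dtype=float), (n,))

    x1_eq, x2_eq = _equilibria_batch(
        replace(p, c11=c11, c12=c12, c21=c21, c22=c22),
        u1.reference_level(), u2.reference_level(),
    )

    if history is None:
        history = np.concatenate([x1_eq + perturb, x2_eq])
    elif np.ndim(history) and np.asarray(history).size == 2 and n > 1:
        h = np.asarray(history, dtype=float)
        history = np.concatenate([np.full(n, h[0]), np.full(n, h[1])])

    ctrl = make_runtime(controller, n=n, dt_ms=cfg.dt, x1_ref=x1_eq) if controller else None
    mu_hold = np.zeros(n)

    n_steps = cfg.n_steps
    theta_log = np.zeros((n_steps + 1, n))
    mu_log = np.zeros((n_steps + 1, n))
    u1_log = np.empty((n_steps + 1, n))
    u2_log = np.empty((n_steps + 1, n))
    if ctrl is not None:
        theta_log[0] = ctrl.theta

    tau1, tau2 = p.tau1, p.tau2
    s1p, s2p = p.s1, p.s2
    m1, b1s, a1s = s1p.m, s1p.b, s1p.scale
    m2, b2s, a2s = s2p.m, s2p.b, s2p.scale
    w1, w2 = p.b1, p.b2
    u1f, u2f = _fast_input(u1), _fast_input(u2)
    exp, clip = np.exp, np.clip

    def rhs(t: float, y: np.ndarray, lagged: np.ndarray) -> np.ndarray:
        x1 = y[:n]
        x2 = y[n:]
        z1 = c11 * lagged[0, :n] - c12 * lagged[1, n:] + w1 * u1f(t) + mu_hold
        z2 = c21 * lagged[2, :n] - c22 * lagged[3, n:] - w2 * u2f(t)
        e1 = exp(clip(-4.0 * z1 / m1, -700.0, 700.0)) * (m1 - b1s)
        e2 = exp(clip(-4.0 * z2 / m2, -700.0, 700.0)) * (m2 - b2s)
        out = np.empty_like(y)
        out[:n] = (-x1 + a1s * m1 * b1s / (b1s + e1)) / tau1
        out[n:] = (-x2 + a2s * m2 * b2s / (b2s + e2)) / tau2
        return out

    def hook(i: int, t: float, y: np.ndarray, buf) -> None:
        if ctrl is not None:
            mu_hold[:] = ctrl.update(t, y[:n])
            theta_log[i] = ctrl.theta
            mu_log[i] = mu_hold
        u1_log[i] = u1f(t)
        u2_log[i] = u2f(t)

    u1_log[0] = u1.value(0.0)
    u2_log[0] = u2.value(0.0)

    sol = integrate_dde(rhs, p.delays, history, cfg, step_hook=hook)
    x1_traj = sol.y[:, :n]
    x2_traj = sol.y[:, n:]

    if check_bounds:
        eps = 1e-6
        if (x1_traj.min() < -eps or x1_traj.max() > s1p.max_rate + eps
                or x2_traj.min() < -eps or x2_traj.max() > s2p.max_rate + eps):
            raise RuntimeError(
                "firing rates left the invariant region [0, a*M]; "
                "check parameters and step size"
            )

    return Trajectory(
        t_ms=sol.t, x1=x1_traj, x2=x2_traj,
        theta=theta_log, mu=mu_log, u1=u1_log, u2=u2_log,
        dt_ms=cfg.dt, x1_eq=x1_eq, x2_eq=x2_eq,
    )
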