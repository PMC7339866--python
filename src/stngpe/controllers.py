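"""Proportional and self-tuning (sigma-modification) DBS control laws.

Feedback on the firing-rate loop acts on the deviation of the STN rate from
its equilibrium, ``mu(t) = -theta * (x1(t) - x1_eq)`` (negative feedback).  The
self-tuning variants adapt the gain::

    tau_theta * theta'(t) = drive(t) - sigma * theta(t)

where the drive is ``|x1 - x1_eq|`` (mode ``adaptive_abs``), the beta biomarker
``beta(x1_t)`` — the peak-to-peak amplitude of the band-pass filtered STN rate
(Butterworth order 5, 15-30 Hz) over the trailing 500 ms window — (mode
``adaptive_beta``), or the half-wave rectified tracking error ``|e|`` of a
measured beta-ARV biomarker (mode ``adaptive_arv``, used with the surrogate
plant, where feedback is positive because larger stimulation suppresses the
biomarker).  The leak ``-sigma*theta`` is the sigma-modification of adaptive
control: the gain grows while pathological activity persists, overtakes the
(unknown) minimal stabilizing gain, and dissipates once activity is suppressed,
so it hovers near the smallest effective value.

The gain ODE is linear in ``theta``; with the drive held over a step it has an
exact solution, and the update below uses that integrating-factor step (exact
for piecewise-constant drive, and trivially clamped at zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_metrics import FilterSpec, design_sos

__all__ = [
    "ControllerConfig",
    "GainBound",
    "controller_output",
    "adaptive_gain_step",
    "beta_drive",
    "error_drive",
    "theta_star_bound",
    "make_runtime",
]

_RATE_MODES = ("off", "proportional", "adaptive_abs", "adaptive_beta")
_ALL_MODES = _RATE_MODES + ("adaptive_arv",)


@dataclass(frozen=True)
class ControllerConfig:
    """Controller mode and tuning constants.

    Parameters
    ----------
    mode : str
        ``off``, ``proportional``, ``adaptive_abs``, ``adaptive_beta`` (firing-
        rate loop, negative feedback) or ``adaptive_arv`` (surrogate plant,
        positive feedback on the measured biomarker).
    theta : float
        Fixed gain for ``proportional`` mode.
    theta0 : float
        Initial gain for adaptive modes (>= 0).
    tau_theta_ms, sigma : float
        Adaptation time constant (ms, > 0) and leak rate (>= 0).  May be arrays
        to run a batch of controllers in parallel.
    target : float
        Desired biomarker suppression level (biomarker units, ``adaptive_arv``).
    window_ms : float
        Trailing window for the beta biomarker drive.
    t_on_ms : float
        Stimulation onset time; the controller is inert before it.
    drive_refresh_ms : float
        Cadence at which the windowed beta drive is recomputed (held between
        refreshes; the gain dynamics are far slower than the simulation step).
    """

    mode: str = "off"
    theta: float | np.ndarray = 0.0
    theta0: float | np.ndarray = 0.0
    tau_theta_ms: float | np.ndarray = 50.0
    sigma: float | np.ndarray = 0.1
    target: float = 0.0
    window_ms: float = 500.0
    t_on_ms: float = 0.0
    drive_refresh_ms: float = 1.0
    filter: FilterSpec | None = None

    def __post_init__(self) -> None:
        if self.mode not in _ALL_MODES:
            raise ValueError(f"unknown controller mode {self.mode!r}")
        if np.any(np.asarray(self.tau_theta_ms) <= 0):
            raise ValueError("tau_theta_ms must be positive")
        if np.any(np.asarray(self.sigma) < 0):
            raise ValueError("sigma must be non-negative")
        if np.any(np.asarray(self.theta0) < 0):
            raise ValueError("theta0 must be non-negative")


@dataclass(frozen=True)
class GainBound:
    """Conservative analytic upper estimate of the minimal stabilizing gain."""

    theta_star: float


def controller_output(cfg: ControllerConfig, theta, signal):
    """Stimulation magnitude for the current gain and measured signal.

    Negative feedback (``mu = -theta * signal``) for the firing-rate modes,
    positive (``mu = +theta * signal``) for the plant-facing ARV mode, zero
    when off.
    """
    if cfg.mode == "off":
        return np.zeros_like(np.asarray(signal, dtype=float)) if np.ndim(signal) else 0.0
    sign = 1.0 if cfg.mode == "adaptive_arv" else -1.0
    return sign * theta * signal


def adaptive_gain_step(theta, drive, sigma, tau_theta_ms, dt_ms):
    """One discrete update of the gain law ``tau_theta theta' = drive - sigma theta``.

    Uses the exact solution with the drive held constant over the step::

        theta <- theta * exp(-sigma dt / tau) + drive * (1 - exp(-sigma dt / tau)) / sigma

    (limit ``theta + drive * dt / tau`` as sigma -> 0), clamped at zero.  All
    arguments broadcast, so batches of controllers advance in one call.
    """
    theta = np.asarray(theta, dtype=float)
    drive = np.asarray(drive, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    tau = np.asarray(tau_theta_ms, dtype=float)
    a = sigma * dt_ms / tau
    decay = np.exp(-a)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(sigma > 0.0, (1.0 - decay) / np.where(sigma > 0.0, sigma, 1.0),
                        dt_ms / tau)
    out = np.maximum(theta * decay + drive * gain, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def beta_drive(
    x1_window: Sequence[float],
    fs_hz: float,
    window_ms: float = 500.0,
    spec: FilterSpec | None = None,
    zi: np.ndarray | None = None,
    return_zi: bool = False,
):
    """Beta biomarker: peak-to-peak of the band-pass filtered signal over the window.

    ``x1_window`` must cover at least ``window_ms``; the drive is the max-min of
    the causally filtered samples.  Pass ``zi`` (and ``return_zi=True``) to
    carry filter state across successive windows, as the in-simulation
    controller does.
    """
    from scipy.signal import sosfilt

    x = np.asarray(x1_window, dtype=float)
    n_req = int(round(window_ms * fs_hz / 1000.0))
    if x.shape[0] < n_req:
        raise ValueError(
            f"window of {x.shape[0]} samples is shorter than {window_ms} ms "
            f"at {fs_hz} Hz ({n_req} samples)"
        )
    if spec is None:
        spec = FilterSpec.beta_butter(fs_hz)
    sos = design_sos(spec)
    if zi is None:
        zi = np.zeros((sos.shape[0], 2))
    y, zf = sosfilt(sos, x, zi=zi)
    drive = float(np.max(y[-n_req:]) - np.min(y[-n_req:]))
    if return_zi:
        return drive, zf
    return drive


def error_drive(biomarker, target, normalize: bool = False):
    """Half-wave rectified tracking error ``max(biomarker - target, 0)``.

    With ``normalize=True`` the error is expressed relative to the target,
    ``max((biomarker - target) / target, 0)``, matching the normalized error
    used by the plant-facing controller and the MSE measure.
    """
    b = np.asarray(biomarker, dtype=float)
    t = np.asarray(target, dtype=float)
    e = (b - t) / t if normalize else b - t
    out = np.maximum(e, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def theta_star_bound(c11: float, c12: float, c21: float, c22: float) -> GainBound:
    """Analytic (conservative) bound ``8 (c11^2 + 4 c21^2 c12^2 / (1 - c22)^2)``.

    Valid in the normalized-slope convention; undefined at ``c22 = 1``.
    """
    if c22 == 1.0:
        raise ValueError("theta* bound is undefined at c22 = 1")
    val = 8.0 * (c11 ** 2 + 4.0 * c21 ** 2 * c12 ** 2 / (1.0 - c22) ** 2)
    return GainBound(theta_star=float(val))


# ---------------------------------------------------------------------------
# Runtime controller used inside simulations
# ---------------------------------------------------------------------------

class _Biquad:
    """Vectorized direct-form-II-transposed SOS chain, one sample per call."""

    def __init__(self, sos: np.ndarray, n: int):
        self.sos = sos
        self.z = np.zeros((sos.shape[0], 2, n))

    def step(self, x: np.ndarray) -> np.ndarray:
        for s in range(self.sos.shape[0]):
            b0, b1, b2, _, a1, a2 = self.sos[s]
            z0, z1 = self.z[s]
            y = b0 * x + z0
            self.z[s, 0] = b1 * x - a1 * y + z1
            self.z[s, 1] = b2 * x - a2 * y
            x = y
        return x


class _RuntimeController:
    """Per-step controller state for closed-loop firing-rate simulations."""

    def __init__(self, cfg: ControllerConfig, n: int, dt_ms: float, x1_ref: np.ndarray):
        if cfg.mode == "adaptive_arv":
            raise ValueError(
                "adaptive_arv is the plant-facing mode; use surrogate_plant.run_scenario"
            )
        self.cfg = cfg
        self.n = n
        self.dt = dt_ms
        self.ref = np.asarray(x1_ref, dtype=float)
        if cfg.mode == "proportional":
            self.theta = np.broadcast_to(np.asarray(cfg.theta, dtype=float), (n,)).copy()
        else:
            self.theta = np.broadcast_to(np.asarray(cfg.theta0, dtype=float), (n,)).copy()
        self.sigma = np.broadcast_to(np.asarray(cfg.sigma, dtype=float), (n,))
        self.tau = np.broadcast_to(np.asarray(cfg.tau_theta_ms, dtype=float), (n,))
        self._drive = np.zeros(n)
        if cfg.mode == "adaptive_beta":
            fs = 1000.0 / dt_ms
            spec = cfg.filter or FilterSpec.beta_butter(fs)
            self._filt = _Biquad(design_sos(spec), n)
            self._win = max(1, int(round(cfg.window_ms / dt_ms)))
            self._ring = np.zeros((self._win, n))
            self._count = 0
            self._refresh = max(1, int(round(cfg.drive_refresh_ms / dt_ms)))

    def update(self, t: float, x1: np.ndarray) -> np.ndarray:
        """Advance gain state to time ``t`` and return mu to hold over the next step."""
        cfg = self.cfg
        if cfg.mode == "off" or t < cfg.t_on_ms:
            return np.zeros(self.n)
        dev = x1 - self.ref
        if cfg.mode == "proportional":
            return -self.theta * dev
        if cfg.mode == "adaptive_abs":
            self._drive = np.abs(dev)
        else:  # adaptive_beta
            y = self._filt.step(dev)
            self._ring[self._count % self._win] = y
            self._count += 1
            if self._count >= self._win and self._count % self._refresh == 0:
                self._drive = self._ring.max(axis=0) - self._ring.min(axis=0)
            elif self._count < self._win:
                self._drive = np.zeros(self.n)
        self.theta = adaptive_gain_step(self.theta, self._drive, self.sigma,
                                        self.tau, self.dt)
        return -self.theta * dev


def make_runtime(cfg: ControllerConfig, n: int, dt_ms: float, x1_ref) -> _RuntimeController:
    """Build the per-step controller state used by :func:`stngpe.model.simulate`."""
    return _RuntimeController(cfg, n=n, dt_ms=dt_ms, x1_ref=np.asarray(x1_ref, dtype=float))
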