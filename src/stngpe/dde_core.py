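"""Fixed-step integration of delay differential equations with constant discrete delays.

The integrator is a classical explicit 4th-order Runge-Kutta scheme in which
delayed state references are resolved from a uniform-grid history buffer.  Every
delay must be an integer multiple of the step ``dt`` (enforced, never rounded),
so delayed lookups at whole steps land exactly on stored samples; lookups at the
half-step stage times fall midway between two stored samples and are resolved by
linear interpolation.  A zero delay refers to the current stage state, which
makes the scheme collapse to plain RK4 for ordinary differential equations.

The state of a DDE at time ``t`` is the history segment ``x_t(s) = x(t + s)``
for ``s`` in ``[-delta_max, 0]``; :class:`HistoryBuffer` is the discrete record
of that segment over the whole integration span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "IntegrationError",
    "IntegratorConfig",
    "HistoryBuffer",
    "DDESolution",
    "lookup_delayed",
    "integrate_dde",
]


class ConfigurationError(ValueError):
    """Invalid integrator setup (bad step, incommensurate delay, ...)."""


class IntegrationError(RuntimeError):
    """Runtime failure during integration (non-finite state, bad lookup)."""


_GRID_TOL = 1e-9


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integration settings.

    Parameters
    ----------
    dt : float
        Step size in ms.  Every model delay must be an integer multiple of it.
    duration : float
        Total integration span in ms, starting at t = 0.
    method : str
        Scheme tag; only ``"rk4"`` is implemented.
    """

    dt: float = 0.1
    duration: float = 1000.0
    method: str = "rk4"

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if not self.duration > 0:
            raise ConfigurationError(f"duration must be positive, got {self.duration}")
        if self.method != "rk4":
            raise ConfigurationError(f"unknown integration method {self.method!r}")

    @property
    def n_steps(self) -> int:
        n = int(round(self.duration / self.dt))
        if abs(n * self.dt - self.duration) > _GRID_TOL * max(1.0, self.duration):
            raise ConfigurationError(
                f"duration {self.duration} ms is not a multiple of dt {self.dt} ms"
            )
        return n


def _delay_steps(delay: float, dt: float) -> int:
    k = delay / dt
    ki = int(round(k))
    if abs(k - ki) > 1e-6:
        raise ConfigurationError(
            f"delay {delay} ms is not an integer multiple of dt {dt} ms"
        )
    return ki


@dataclass
class HistoryBuffer:
    """Uniform-grid record of the trajectory covering ``[-max_delay, t]``.

    Row ``i`` holds the state at ``t = (i - n_hist) * dt`` where ``n_hist =
    max_delay / dt``.  The buffer is pre-allocated for the whole run; ``filled``
    is the index of the most recently written row.
    """

    dt: float
    n_state: int
    max_delay: float
    n_steps: int
    data: np.ndarray = field(init=False)
    n_hist: int = field(init=False)
    filled: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_hist = _delay_steps(self.max_delay, self.dt)
        self.data = np.empty((self.n_hist + self.n_steps + 1, self.n_state))
        self.filled = -1

    def seed(self, initial: Callable[[float], np.ndarray] | np.ndarray) -> None:
        """Fill the initial segment ``[-max_delay, 0]`` from a constant or a function."""
        if callable(initial):
            for i in range(self.n_hist + 1):
                t = (i - self.n_hist) * self.dt
                self.data[i] = np.asarray(initial(t), dtype=float)
        else:
            self.data[: self.n_hist + 1] = np.asarray(initial, dtype=float)
        self.filled = self.n_hist

    def time_of_row(self, i: int) -> float:
        return (i - self.n_hist) * self.dt

    @property
    def latest_time(self) -> float:
        return self.time_of_row(self.filled)

    def append(self, y: np.ndarray) -> None:
        self.filled += 1
        self.data[self.filled] = y

    def lookup(self, t: float, delay: float = 0.0) -> np.ndarray:
        """State at ``t - delay``; exact on grid points, linear between them.

        Raises :class:`IntegrationError` if ``t - delay`` lies outside the
        covered span — there is no silent extrapolation.
        """
        u = t - delay
        pos = u / self.dt + self.n_hist
        lo, hi = 0, self.filled
        if pos < lo - _GRID_TOL or pos > hi + _GRID_TOL:
            raise IntegrationError(
                f"delayed lookup at t - delay = {u} ms is outside the covered "
                f"span [{self.time_of_row(lo)}, {self.latest_time}] ms"
            )
        i0 = int(np.floor(pos))
        frac = pos - i0
        if i0 >= hi:
            return self.data[hi].copy()
        if frac <= _GRID_TOL:
            return self.data[i0].copy()
        if frac >= 1.0 - _GRID_TOL:
            return self.data[i0 + 1].copy()
        return (1.0 - frac) * self.data[i0] + frac * self.data[i0 + 1]


def lookup_delayed(history: HistoryBuffer, t: float, delay: float) -> np.ndarray:
    """Resolve the delayed state ``x(t - delay)`` from a history buffer."""
    return history.lookup(t, delay)


@dataclass(frozen=True)
class DDESolution:
    """Raw integration output: times (ms) and states on ``[0, duration]``."""

    t: np.ndarray
    y: np.ndarray


RHS = Callable[[float, np.ndarray, np.ndarray], np.ndarray]
StepHook = Callable[[int, float, np.ndarray, HistoryBuffer], None]


def integrate_dde(
    rhs: RHS,
    delays: Sequence[float],
    history: Callable[[float], np.ndarray] | np.ndarray,
    config: IntegratorConfig,
    step_hook: StepHook | None = None,
) -> DDESolution:
    """Integrate ``y'(t) = rhs(t, y, lagged)`` with constant discrete delays.

    Parameters
    ----------
    rhs : callable
        ``rhs(t, y, lagged) -> dy/dt`` where ``lagged[j]`` is the state at
        ``t - delays[j]``.  A zero delay is served the current (stage) state.
    delays : sequence of float
        Delays in ms; each must be >= 0 and an integer multiple of ``config.dt``.
    history : array or callable
        Initial history on ``[-max(delays), 0]``: a constant state vector or a
        function of time returning the state.
    config : IntegratorConfig
    step_hook : callable, optional
        ``step_hook(i, t, y, buffer)`` invoked after every accepted step, e.g.
        to advance coupled non-delayed controller state.  Mutations made by the
        hook are visible to ``rhs`` through enclosing scope, with the resulting
        inputs held constant over each subsequent step (zero-order hold).

    Returns
    -------
    DDESolution
        Grid times on ``[0, duration]`` and the corresponding states.
    """
    delays = [float(d) for d in delays]
    if any(d < 0 for d in delays):
        raise ConfigurationError("delays must be non-negative")
    dt = config.dt
    ks = [_delay_steps(d, dt) for d in delays]
    n_steps = config.n_steps
    max_delay = max(delays, default=0.0)

    if callable(history):
        y0 = np.atleast_1d(np.asarray(history(0.0), dtype=float))
    else:
        y0 = np.atleast_1d(np.asarray(history, dtype=float))
    n_state = y0.size

    buf = HistoryBuffer(dt=dt, n_state=n_state, max_delay=max_delay, n_steps=n_steps)
    if callable(history):
        buf.seed(lambda t: np.atleast_1d(np.asarray(history(t), dtype=float)))
    else:
        buf.seed(y0)

    data = buf.data
    ks_arr = np.asarray(ks, dtype=int)
    zero_lag = ks_arr == 0
    any_zero = bool(zero_lag.any())
    lagged = np.empty((len(ks), n_state))

    def fill_lagged(row: int, stage: int, ystage: np.ndarray) -> np.ndarray:
        # stage 0 -> offset 0; stage 1 -> offset dt/2; stage 2 -> offset dt
        # for zero delays "row + 1" would read the not-yet-written row; clamp,
        # the value is overridden with the stage state below anyway
        if stage == 0:
            lagged[:] = data[row - ks_arr]
        elif stage == 2:
            lagged[:] = data[np.minimum(row + 1 - ks_arr, row)]
        else:
            np.add(data[row - ks_arr],
                   data[np.minimum(row + 1 - ks_arr, row)], out=lagged)
            np.multiply(lagged, 0.5, out=lagged)
        if any_zero:
            lagged[zero_lag] = ystage
        return lagged

    half = 0.5 * dt
    sixth = dt / 6.0
    for i in range(n_steps):
        t = i * dt
        row = buf.n_hist + i
        y = data[row]
        k1 = rhs(t, y, fill_lagged(row, 0, y))
        y2 = y + half * k1
        k2 = rhs(t + half, y2, fill_lagged(row, 1, y2))
        y3 = y + half * k2
        k3 = rhs(t + half, y3, fill_lagged(row, 1, y3))
        y4 = y + dt * k3
        k4 = rhs(t + dt, y4, fill_lagged(row, 2, y4))
        ynew = y + sixth * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(ynew)):
            raise IntegrationError(
                f"non-finite state produced at t = {t + dt:.6g} ms"
            )
        buf.append(ynew)
        if step_hook is not None:
            step_hook(i + 1, t + dt, ynew, buf)

    t_grid = np.arange(n_steps + 1) * dt
    return DDESolution(t=t_grid, y=data[buf.n_hist :].copy())
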