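"""Surrogate plant: a synthetic stand-in for the closed-loop observable of a
detailed conductance-based basal-ganglia network.

The plant exposes what a clinical closed-loop DBS system sees: a beta-band
average-rectified-value (ARV) biomarker from the STN LFP that decreases
monotonically and saturates as stimulation amplitude increases.  It is a
descriptive model shaped by three ingredients:

* a logistic suppression curve in effective stimulation amplitude, with a
  configurable floor (residual beta that stimulation cannot remove);
* electrode impedance entering as ``I_eff = I * Z_E(0) / Z_E(t)`` for a
  current-controlled stimulus, so impedance growth weakens a fixed current and
  demands a larger controller gain;
* a first-order lag between stimulation changes and biomarker response, plus
  additive Gaussian measurement noise on the ARV samples.

Three scenario schedules exercise controller adaptation over a 130 s horizon:
varying the suppression target, switching the background beta level, and
ramping the electrode impedance.  The controller runs at the biomarker epoch
cadence (100 ms) with positive feedback ``I_DBS = theta * ARV`` and the
sigma-modification gain law driven by the half-wave rectified normalized
tracking error; defaults tau_theta = 100 ms and sigma = 0.00875.

Absolute performance numbers of the detailed network are out of scope; the
plant reproduces the qualitative orderings (adaptive control tracks through
operating-point changes that defeat any single fixed gain, at intermediate
power cost).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .controllers import ControllerConfig, adaptive_gain_step, error_drive
from .signal_metrics import PerformanceReport, mse, power_consumption

__all__ = [
    "PiecewiseSchedule",
    "PlantParams",
    "PlantState",
    "ScenarioSpec",
    "ScenarioResult",
    "plant_step",
    "run_scenario",
    "compare_controllers",
]


@dataclass(frozen=True)
class PiecewiseSchedule:
    """Piecewise schedule over time (s): constant segments or linear ramps.

    ``times`` are segment breakpoints (starting at 0); ``values`` the value at
    each breakpoint.  ``interp="previous"`` holds each value until the next
    breakpoint; ``interp="linear"`` ramps between breakpoints.
    """

    times: tuple
    values: tuple
    interp: str = "previous"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values) or not self.times:
            raise ValueError("times and values must be equal-length, non-empty")
        if list(self.times) != sorted(self.times):
            raise ValueError("breakpoints must be increasing")
        if self.interp not in ("previous", "linear"):
            raise ValueError(f"unknown interpolation {self.interp!r}")

    def value(self, t: float) -> float:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if self.interp == "previous":
            k = int(np.searchsorted(times, t, side="right")) - 1
            return float(values[max(k, 0)])
        return float(np.interp(t, times, values))

    __call__ = value

    @classmethod
    def constant(cls, value: float) -> "PiecewiseSchedule":
        return cls(times=(0.0,), values=(float(value),))


#: Background beta ARV at full pathological drive (uV).
BACKGROUND_HIGH_UV = 0.35
#: Background beta ARV during low-beta periods (uV).
BACKGROUND_LOW_UV = 0.08


@dataclass(frozen=True)
class PlantParams:
    """Suppression-curve, noise, lag and impedance parameters of the plant.

    The defaults put the gain needed to hold typical targets in the 5-30
    range and keep the sigma-modification leak's steady tracking offset small
    relative to the targets; they are study conditions, not tuning knobs.
    """

    background_uv: PiecewiseSchedule = field(
        default_factory=lambda: PiecewiseSchedule.constant(BACKGROUND_HIGH_UV))
    impedance_kohm: PiecewiseSchedule = field(
        default_factory=lambda: PiecewiseSchedule.constant(0.5))
    i_half_ma: float = 0.4      # stimulation amplitude at half suppression
    width_ma: float = 0.15      # logistic width of the suppression curve
    floor: float = 0.05         # residual fraction of background at full drive
    noise_uv: float = 0.05 * BACKGROUND_HIGH_UV  # additive ARV sample noise (s.d.)
    lag_ms: float = 500.0       # first-order response lag
    dt_ms: float = 1.0          # internal plant step

    def __post_init__(self) -> None:
        if self.floor < 0 or self.floor >= 1:
            raise ValueError("floor must be in [0, 1)")
        if self.lag_ms <= 0 or self.dt_ms <= 0:
            raise ValueError("lag and step must be positive")

    def suppression(self, i_eff_ma) -> np.ndarray | float:
        """Monotone non-increasing fraction of background beta remaining."""
        z = (np.asarray(i_eff_ma, dtype=float) - self.i_half_ma) / self.width_ma
        s0 = 1.0 / (1.0 + np.exp(-self.i_half_ma / self.width_ma))  # exact 1 at I=0
        out = self.floor + (1.0 - self.floor) / (1.0 + np.exp(z)) / s0
        out = np.minimum(out, 1.0)
        return float(out) if np.ndim(i_eff_ma) == 0 else out


@dataclass
class PlantState:
    """Lagged plant response: current suppression fraction (1 = no suppression)."""

    suppression: float = 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Target / background-beta / impedance schedule for one scenario run."""

    name: str
    target_uv: PiecewiseSchedule
    background_uv: PiecewiseSchedule
    impedance_kohm: PiecewiseSchedule
    duration_s: float = 130.0

    def __post_init__(self) -> None:
        for sched in (self.target_uv, self.background_uv, self.impedance_kohm):
            if sched.times[0] < 0 or sched.times[-1] > self.duration_s:
                raise ValueError("schedule breakpoints must lie in [0, duration]")

    # The three standard scenarios ----------------------------------------

    @classmethod
    def target_variation(cls) -> "ScenarioSpec":
        """Fixed high background; suppression target stepped over time."""
        return cls(
            name="target_variation",
            target_uv=PiecewiseSchedule(times=(0.0, 10.0, 40.0, 70.0, 100.0),
                                        values=(10.0, 0.2, 0.05, 0.15, 10.0)),
            background_uv=PiecewiseSchedule.constant(BACKGROUND_HIGH_UV),
            impedance_kohm=PiecewiseSchedule.constant(0.5),
        )

    @classmethod
    def beta_variation(cls) -> "ScenarioSpec":
        """Fixed target 0.1 uV; background beta switched low/high."""
        return cls(
            name="beta_variation",
            target_uv=PiecewiseSchedule.constant(0.1),
            background_uv=PiecewiseSchedule(
                times=(0.0, 10.0, 40.0, 70.0, 100.0),
                values=(BACKGROUND_LOW_UV, BACKGROUND_HIGH_UV, BACKGROUND_LOW_UV,
                        BACKGROUND_HIGH_UV, BACKGROUND_LOW_UV)),
            impedance_kohm=PiecewiseSchedule.constant(0.5),
        )

    @classmethod
    def impedance_variation(cls) -> "ScenarioSpec":
        """Fixed target and background; impedance 0.5 kOhm, ramping to 2.5 by 130 s."""
        return cls(
            name="impedance_variation",
            target_uv=PiecewiseSchedule.constant(0.1),
            background_uv=PiecewiseSchedule.constant(BACKGROUND_HIGH_UV),
            impedance_kohm=PiecewiseSchedule(times=(0.0, 30.0, 130.0),
                                             values=(0.5, 0.5, 2.5),
                                             interp="linear"),
        )

    @classmethod
    def by_name(cls, name: str) -> "ScenarioSpec":
        try:
            return {
                "target_variation": cls.target_variation,
                "beta_variation": cls.beta_variation,
                "impedance_variation": cls.impedance_variation,
            }[name]()
        except KeyError:
            raise ValueError(f"unknown scenario {name!r}") from None


def plant_step(
    state: PlantState,
    i_dbs_ma: float,
    params: PlantParams,
    t_s: float,
    dt_ms: float,
    rng: np.random.Generator | None = None,
) -> tuple[float, PlantState]:
    """Advance the plant one internal step; returns (ARV sample in uV, state).

    The suppression fraction relaxes toward the static curve value at the
    current effective stimulation with the configured first-order lag; the ARV
    sample is background * suppression plus measurement noise (if ``rng``).
    """
    if i_dbs_ma < 0:
        raise ValueError("stimulation amplitude must be non-negative")
    z0 = params.impedance_kohm(0.0)
    z = params.impedance_kohm(t_s)
    i_eff = i_dbs_ma * z0 / z
    target = params.suppression(i_eff)
    alpha = 1.0 - np.exp(-dt_ms / params.lag_ms)
    new_s = state.suppression + alpha * (target - state.suppression)
    arv = params.background_uv(t_s) * new_s
    if rng is not None and params.noise_uv > 0:
        arv += params.noise_uv * rng.standard_normal()
    return float(max(arv, 0.0)), PlantState(suppression=float(new_s))


@dataclass(frozen=True)
class ScenarioResult:
    """Epoch-cadence traces and the performance report of one scenario run."""

    spec: ScenarioSpec
    t_s: np.ndarray
    target_uv: np.ndarray
    arv_uv: np.ndarray
    idbs_ma: np.ndarray
    theta: np.ndarray
    ze_kohm: np.ndarray
    report: PerformanceReport

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_s": self.t_s,
            "target": self.target_uv,
            "arv": self.arv_uv,
            "idbs_ma": self.idbs_ma,
            "theta": self.theta,
            "ze_kohm": self.ze_kohm,
        })


def _run_loop(
    spec: ScenarioSpec,
    controller: ControllerConfig,
    params: PlantParams,
    rng: np.random.Generator,
    epoch_ms: float = 100.0,
) -> ScenarioResult:
    dt = params.dt_ms
    steps_per_epoch = max(1, int(round(epoch_ms / dt)))
    n_epochs = int(round(spec.duration_s * 1000.0 / epoch_ms))
    eff_params = replace(params, background_uv=spec.background_uv,
                         impedance_kohm=spec.impedance_kohm)

    mode = controller.mode
    theta = float(np.asarray(controller.theta0)) if mode == "adaptive_arv" \
        else float(np.asarray(controller.theta))
    state = PlantState()
    i_dbs = 0.0

    t_out = np.empty(n_epochs)
    target_out = np.empty(n_epochs)
    arv_out = np.empty(n_epochs)
    i_out = np.empty(n_epochs)
    theta_out = np.empty(n_epochs)
    z_out = np.empty(n_epochs)
    err_norm = np.empty(n_epochs)

    t_ms = 0.0
    for ep in range(n_epochs):
        acc = 0.0
        for _ in range(steps_per_epoch):
            t_ms += dt
            sample, state = plant_step(state, i_dbs, eff_params, t_ms / 1000.0,
                                       dt, rng)
            acc += sample
        arv = acc / steps_per_epoch
        t_s = t_ms / 1000.0
        target = spec.target_uv(t_s)
        e_norm = (arv - target) / target
        if mode == "adaptive_arv":
            drive = error_drive(arv, target, normalize=True)
            theta = adaptive_gain_step(theta, drive, controller.sigma,
                                       controller.tau_theta_ms, epoch_ms)
            i_dbs = max(theta * arv, 0.0)
        elif mode == "proportional":
            i_dbs = max(theta * arv, 0.0)
        elif mode == "off":
            i_dbs = 0.0
        else:
            raise ValueError(
                f"controller mode {mode!r} is not a plant-facing mode"
            )
        t_out[ep] = t_s
        target_out[ep] = target
        arv_out[ep] = arv
        i_out[ep] = i_dbs
        theta_out[ep] = theta
        z_out[ep] = spec.impedance_kohm(t_s)
        err_norm[ep] = e_norm

    mse_raw = mse(err_norm, dt=epoch_ms / 1000.0)
    pc = power_consumption(i_out, z_out, dt=epoch_ms / 1000.0)
    report = PerformanceReport(label=mode, mse_raw=mse_raw, mse_pct=np.nan, pc_uw=pc)
    return ScenarioResult(spec=spec, t_s=t_out, target_uv=target_out,
                          arv_uv=arv_out, idbs_ma=i_out, theta=theta_out,
                          ze_kohm=z_out, report=report)


def run_scenario(
    spec: ScenarioSpec,
    controller: ControllerConfig,
    params: PlantParams | None = None,
    seed: int = 0,
    epoch_ms: float = 100.0,
    mse_off: float | None = None,
) -> ScenarioResult:
    """Run one closed-loop scenario and report MSE (% of stimulation-off) and PC.

    The stimulation-off reference uses the same seed, hence the same noise
    realization; identical seeds give identical results.  Pass ``mse_off`` (the
    raw stimulation-off MSE for this scenario and seed) to skip recomputing the
    reference when comparing several controllers.
    """
    if params is None:
        params = PlantParams()
    res = _run_loop(spec, controller, params, np.random.default_rng(seed),
                    epoch_ms=epoch_ms)
    if controller.mode == "off":
        mse_pct = 100.0
    else:
        if mse_off is None:
            off = _run_loop(spec, ControllerConfig(mode="off"), params,
                            np.random.default_rng(seed), epoch_ms=epoch_ms)
            mse_off = off.report.mse_raw
        mse_pct = 100.0 * res.report.mse_raw / mse_off
    report = PerformanceReport(label=res.report.label, mse_raw=res.report.mse_raw,
                               mse_pct=float(mse_pct), pc_uw=res.report.pc_uw)
    return ScenarioResult(spec=res.spec, t_s=res.t_s, target_uv=res.target_uv,
                          arv_uv=res.arv_uv, idbs_ma=res.idbs_ma,
                          theta=res.theta, ze_kohm=res.ze_kohm, report=report)


def compare_controllers(
    spec: ScenarioSpec,
    controllers: Sequence[tuple[str, ControllerConfig]],
    params: PlantParams | None = None,
    seed: int = 0,
):
    """Run several controllers on one scenario; returns a summary DataFrame
    (controller label, MSE as % of stimulation-off, power in uW)."""
    import pandas as pd

    if params is None:
        params = PlantParams()
    off = _run_loop(spec, ControllerConfig(mode="off"), params,
                    np.random.default_rng(seed))
    rows = []
    for label, cfg in controllers:
        res = run_scenario(spec, cfg, params=params, seed=seed,
                           mse_off=off.report.mse_raw)
        rows.append((label, res.report.mse_pct, res.report.pc_uw))
    return pd.DataFrame(rows, columns=["controller", "mse_pct", "power_uw"])
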