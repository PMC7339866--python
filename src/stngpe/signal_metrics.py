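"""Biomarker extraction filters and controller performance measures.

Three band-pass designs recur in this package:

* beta drive filter — Butterworth, order 5, 15-30 Hz, applied causally to the
  STN rate deviation to form the self-tuning controller's beta biomarker;
* oscillation-map filter — Butterworth, order 5, 8 Hz bandwidth centered on
  20 Hz (16-24 Hz), applied zero-phase for offline amplitude maps;
* ARV filter — Chebyshev type I, order 4, 8 Hz bandwidth centered on 25 Hz
  (0.5 dB passband ripple, a conventional default recorded here since the
  ripple is otherwise a free choice), used for the LFP-style beta
  average-rectified-value biomarker.

Performance of a closed-loop stimulation run is summarized by the mean squared
tracking error MSE = (1/T) \\int e(t)^2 dt (with e the normalized error
(biomarker - target)/target, so the measure is scale-free) and the mean
electrical power PC = (1/T) \\int Z_E(t) I_DBS(t)^2 dt.  With impedance in
kOhm and current in mA, Z*I^2 is in mW; PC is reported in uW.  Integrals use
the trapezoidal rule on the sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FilterSpec",
    "design_sos",
    "bandpass",
    "sliding_peak_to_peak",
    "beta_arv",
    "mse",
    "power_consumption",
    "PerformanceReport",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter design: family, order, band edges and sampling rate."""

    family: str  # "butterworth" | "chebyshev1"
    order: int
    low_hz: float
    high_hz: float
    fs_hz: float
    ripple_db: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ("butterworth", "chebyshev1"):
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        nyq = self.fs_hz / 2.0
        if not (0.0 < self.low_hz < self.high_hz < nyq):
            raise ValueError(
                f"band ({self.low_hz}, {self.high_hz}) Hz must lie inside "
                f"(0, {nyq}) Hz at fs = {self.fs_hz} Hz"
            )

    @classmethod
    def beta_butter(cls, fs_hz: float) -> "FilterSpec":
        """Controller beta-drive filter: Butterworth order 5, 15-30 Hz."""
        return cls("butterworth", 5, 15.0, 30.0, fs_hz)

    @classmethod
    def map_butter(cls, fs_hz: float) -> "FilterSpec":
        """Oscillation-map filter: Butterworth order 5, 8 Hz band centered 20 Hz."""
        return cls("butterworth", 5, 16.0, 24.0, fs_hz)

    @classmethod
    def arv_cheby(cls, fs_hz: float) -> "FilterSpec":
        """ARV biomarker filter: Chebyshev-I order 4, 8 Hz band centered 25 Hz."""
        return cls("chebyshev1", 4, 21.0, 29.0, fs_hz)


def design_sos(spec: FilterSpec) -> np.ndarray:
    """Second-order-section coefficients for the given band-pass design."""
    from scipy import signal

    wn = (spec.low_hz, spec.high_hz)
    if spec.family == "butterworth":
        return signal.butter(spec.order, wn, btype="bandpass", fs=spec.fs_hz,
                             output="sos")
    return signal.cheby1(spec.order, spec.ripple_db, wn, btype="bandpass",
                         fs=spec.fs_hz, output="sos")


def bandpass(x, spec: FilterSpec, mode: str = "causal") -> np.ndarray:
    """Band-pass filter a sampled series.

    ``mode="causal"`` uses a forward-only pass (what a real-time controller
    sees); ``mode="zero-phase"`` uses forward-backward filtering for offline
    analyses where phase distortion matters.
    """
    from scipy import signal

    x = np.asarray(x, dtype=float)
    if x.shape[0] <= 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    sos = design_sos(spec)
    if mode == "causal":
        return signal.sosfilt(sos, x, axis=0)
    if mode == "zero-phase":
        return signal.sosfiltfilt(sos, x, axis=0)
    raise ValueError(f"unknown filtering mode {mode!r}")


def sliding_peak_to_peak(x, window_ms: float, dt_ms: float) -> np.ndarray:
    """Instantaneous peak-to-peak amplitude over a trailing window.

    At each sample, max - min of the samples in ``[t - window, t]`` (growing
    window near the start).  Zero for constant signals.
    """
    import pandas as pd

    x = np.asarray(x, dtype=float)
    w = max(1, int(round(window_ms / dt_ms)) + 1)
    s = pd.Series(x)
    roll = s.rolling(window=w, min_periods=1)
    return (roll.max() - roll.min()).to_numpy()


def beta_arv(x, spec: FilterSpec, epoch_ms: float = 100.0,
             mode: str = "causal") -> tuple[np.ndarray, np.ndarray]:
    """Average rectified value of the band-filtered signal per non-overlapping epoch.

    Returns ``(t_end_ms, arv)`` where ``t_end_ms[i]`` is the right edge of
    epoch ``i`` (epochs are right-aligned; a controller consumes the latest
    completed epoch).  Trailing samples short of a full epoch are dropped.
    """
    x = np.asarray(x, dtype=float)
    filt = np.abs(bandpass(x, spec, mode=mode))
    n_ep = max(1, int(round(epoch_ms * spec.fs_hz / 1000.0)))
    n_full = x.shape[0] // n_ep
    if n_full == 0:
        raise ValueError("series shorter than one epoch")
    arv = filt[: n_full * n_ep].reshape(n_full, n_ep).mean(axis=1)
    t_end = (np.arange(1, n_full + 1) * n_ep) * (1000.0 / spec.fs_hz)
    return t_end, arv


def mse(e, dt=None, t=None) -> float:
    """Time-averaged squared error ``(1/T) \\int e(t)^2 dt`` (trapezoidal rule)."""
    e = np.asarray(e, dtype=float)
    if t is not None:
        t = np.asarray(t, dtype=float)
        span = t[-1] - t[0]
        return float(np.trapezoid(e ** 2, t) / span)
    if dt is None:
        dt = 1.0
    span = dt * (e.shape[0] - 1)
    return float(np.trapezoid(e ** 2, dx=dt) / span)


def power_consumption(i_dbs, z_e, dt=None, t=None) -> float:
    """Mean electrical power ``(1/T) \\int Z_E I^2 dt`` in uW (Z in kOhm, I in mA)."""
    i_dbs = np.asarray(i_dbs, dtype=float)
    z_e = np.broadcast_to(np.asarray(z_e, dtype=float), i_dbs.shape)
    if np.any(z_e < 0):
        raise ValueError("electrode impedance must be non-negative")
    p_mw = z_e * i_dbs ** 2
    if t is not None:
        t = np.asarray(t, dtype=float)
        mean_mw = np.trapezoid(p_mw, t) / (t[-1] - t[0])
    else:
        if dt is None:
            dt = 1.0
        mean_mw = np.trapezoid(p_mw, dx=dt) / (dt * (i_dbs.shape[0] - 1))
    return float(mean_mw * 1000.0)


@dataclass(frozen=True)
class PerformanceReport:
    """Tracking error and power summary for one controller run.

    ``mse_pct`` is the MSE as a percentage of the stimulation-off MSE of the
    same scenario (the convention used for controller comparisons); ``pc_uw``
    the mean power in uW.
    """

    label: str
    mse_raw: float
    mse_pct: float
    pc_uw: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mse_raw": self.mse_raw,
            "mse_pct": self.mse_pct,
            "pc_uw": self.pc_uw,
        }
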