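"""Model characterization: oscillation maps over coupling space and nonlinear
Bode (frequency-response) profiles under sinusoidal cortical drive.

The oscillation map integrates the loop on a grid of (c12, c21) couplings and
records, per grid cell and population, the steady-state beta-band oscillation
amplitude (peak-to-peak of the 16-24 Hz filtered rate after the transient),
normalized to [0, 1] separately per population panel.

The Bode profile drives the entrainable loop with a sinusoidal cortical input
of fixed mean and amplitude at a range of frequencies and reports, per
frequency and population, the ratio of the steady-state output oscillation
amplitude (half the peak-to-peak) to the input amplitude.  Because the loop is
nonlinear, the profile depends on the input mean and amplitude — the resonance
is more pronounced for stronger mean drive.  For small input amplitudes the
ratio approaches the magnitude of the transfer function of the linearization
about the operating point, with each delay contributing ``exp(-i w d)``.

All frequencies of one profile are integrated as a single vectorized batch
with a common settle time; cells whose steady-state output is not locked to
the input frequency are flagged, not silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .controllers import ControllerConfig
from .dde_core import IntegratorConfig
from .model import (
    DEFAULT_U2,
    InputSignal,
    LoopParams,
    Trajectory,
    find_equilibrium,
    activation_slope,
    simulate,
)
from .signal_metrics import FilterSpec, bandpass

__all__ = [
    "dominant_frequency",
    "SweepResult",
    "oscillation_map",
    "BodeResult",
    "bode_profile",
    "linearized_transfer",
]


def dominant_frequency(
    x,
    fs_hz: float,
    transient_ms: float = 1000.0,
    flat_tol: float = 1e-9,
) -> float | None:
    """Frequency (Hz) of the largest non-DC spectral peak after the transient.

    Returns ``None`` for a flat signal (peak-to-peak below ``flat_tol`` relative
    to the signal scale) rather than 0.  Resolution is one FFT bin,
    ``fs / n_samples``; callers needing the bin width can compute it the same
    way.
    """
    x = np.asarray(x, dtype=float)
    n_skip = int(round(transient_ms * fs_hz / 1000.0))
    seg = x[n_skip:]
    if seg.size < 8:
        raise ValueError("post-transient span too short for spectral analysis")
    scale = max(1.0, np.max(np.abs(seg)))
    if np.ptp(seg) < flat_tol * scale:
        return None
    seg = seg - seg.mean()
    spec = np.abs(np.fft.rfft(seg))
    freqs = np.fft.rfftfreq(seg.size, d=1.0 / fs_hz)
    k = 1 + int(np.argmax(spec[1:]))
    return float(freqs[k])


def _steady_amplitudes(traj: Trajectory, measure_ms: float,
                       spec: FilterSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell steady-state peak-to-peak of x1 and x2 over the final window,
    optionally band-pass filtered (zero-phase) first."""
    n_meas = int(round(measure_ms / traj.dt_ms))
    out = []
    for arr in (traj.x1, traj.x2):
        seg = arr[-n_meas:]
        if spec is not None:
            seg = bandpass(seg, spec, mode="zero-phase")
        out.append(np.ptp(seg, axis=0))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Oscillation maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    """Beta-band amplitude over a (c12, c21) grid, normalized per population.

    ``amp_stn``/``amp_gpe`` have shape ``(len(c12_values), len(c21_values))``
    and each panel's maximum equals 1 (unless the whole panel is flat, in which
    case it is left at zero and ``panel_max`` records the raw scale).  Failed
    cells are NaN and listed in ``failed``.
    """

    c12_values: np.ndarray
    c21_values: np.ndarray
    amp_stn: np.ndarray
    amp_gpe: np.ndarray
    panel_max: tuple[float, float]
    failed: tuple[tuple[int, int], ...] = ()

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, amp in (("stn", self.amp_stn), ("gpe", self.amp_gpe)):
            for i, c12 in enumerate(self.c12_values):
                for j, c21 in enumerate(self.c21_values):
                    rows.append((float(c12), float(c21), name, float(amp[i, j])))
        return pd.DataFrame(rows, columns=["c12", "c21", "population", "amplitude"])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for a, (name, amp) in zip(ax, (("STN", self.amp_stn), ("GPe", self.amp_gpe))):
            im = a.pcolormesh(self.c21_values, self.c12_values, amp,
                              shading="nearest", vmin=0.0, vmax=1.0)
            a.set_xlabel("c21")
            a.set_title(name)
        ax[0].set_ylabel("c12")
        plt.colorbar(im, ax=list(ax), label="normalized beta amplitude")
        return ax


def oscillation_map(
    template: LoopParams,
    c12_values,
    c21_values,
    u1: float = 27.0,
    u2: float = DEFAULT_U2,
    duration_ms: float = 5000.0,
    measure_ms: float = 2000.0,
    dt_ms: float = 0.1,
    filter_spec: FilterSpec | None = None,
) -> SweepResult:
    """Steady-state beta-band amplitude map over a coupling grid.

    Each cell is simulated from a slightly perturbed equilibrium history for
    ``duration_ms``; the last ``measure_ms`` are band-pass filtered (default
    Butterworth order 5, 16-24 Hz, zero-phase) and the per-population
    peak-to-peak recorded, then normalized per panel.
    """
    c12_values = np.asarray(c12_values, dtype=float)
    c21_values = np.asarray(c21_values, dtype=float)
    grid12, grid21 = np.meshgrid(c12_values, c21_values, indexing="ij")
    p = replace(template, c12=grid12.ravel(), c21=grid21.ravel())
    cfg = IntegratorConfig(dt=dt_ms, duration=duration_ms)
    if filter_spec is None:
        filter_spec = FilterSpec.map_butter(1000.0 / dt_ms)

    shape = grid12.shape
    failed: list[tuple[int, int]] = []
    try:
        traj = _run_map_batch(p, u1, u2, cfg)
        amp1, amp2 = _steady_amplitudes(traj, measure_ms, filter_spec)
        amp1 = amp1.reshape(shape)
        amp2 = amp2.reshape(shape)
    except Exception:
        # fall back to per-cell integration so one bad cell is flagged, not fatal
        amp1 = np.full(shape, np.nan)
        amp2 = np.full(shape, np.nan)
        for i in range(shape[0]):
            for j in range(shape[1]):
                cell = replace(template, c12=grid12[i, j], c21=grid21[i, j])
                try:
                    traj = _run_map_batch(cell, u1, u2, cfg)
                    a1, a2 = _steady_amplitudes(traj, measure_ms, filter_spec)
                    amp1[i, j], amp2[i, j] = a1[0], a2[0]
                except Exception:
                    failed.append((i, j))

    maxes = []
    panels = []
    for amp in (amp1, amp2):
        m = np.nanmax(amp)
        maxes.append(float(m))
        panels.append(amp / m if m > 0 else amp)
    return SweepResult(
        c12_values=c12_values, c21_values=c21_values,
        amp_stn=panels[0], amp_gpe=panels[1],
        panel_max=(maxes[0], maxes[1]), failed=tuple(failed),
    )


def _run_map_batch(p: LoopParams, u1: float, u2: float, cfg: IntegratorConfig) -> Trajectory:
    """Integrate a (possibly batched) map cell from a nudged equilibrium history.

    The nudge (+1 pulses/s on x1) kicks cells in the unstable regime off the
    fixed point so the limit cycle develops within the simulated span.
    """
    from .model import _equilibria_batch  # internal reuse

    n = p.batch_size
    x1_eq, x2_eq = _equilibria_batch(p, u1, u2)
    history = np.concatenate([x1_eq + 1.0, x2_eq])
    return simulate(
        p,
        InputSignal.constant(u1),
        InputSignal.constant(u2),
        cfg=cfg,
        history=history,
    )


# ---------------------------------------------------------------------------
# Bode profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BodeResult:
    """Amplitude-ratio profile of the loop under sinusoidal cortical drive."""

    freqs_hz: np.ndarray
    input_mean: float
    input_amplitude: float
    ratio_stn: np.ndarray
    ratio_gpe: np.ndarray
    controller: str
    entrained: np.ndarray
    dominant_hz: np.ndarray

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, ratio in (("stn", self.ratio_stn), ("gpe", self.ratio_gpe)):
            for k, f in enumerate(self.freqs_hz):
                rows.append((float(f), name, float(ratio[k]), self.controller,
                             bool(self.entrained[k])))
        return pd.DataFrame(
            rows, columns=["freq_hz", "population", "ratio", "controller", "entrained"]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.freqs_hz, self.ratio_stn, label=f"STN ({self.controller})")
        ax.plot(self.freqs_hz, self.ratio_gpe, label=f"GPe ({self.controller})")
        ax.set_xlabel("input frequency (Hz)")
        ax.set_ylabel("amplitude ratio (output/input)")
        ax.legend()
        return ax


def bode_profile(
    p: LoopParams,
    freqs_hz,
    input_mean: float,
    input_amplitude: float,
    controller: ControllerConfig | None = None,
    u2: float = DEFAULT_U2,
    settle_ms: float = 3000.0,
    measure_ms: float = 2000.0,
    dt_ms: float = 0.1,
) -> BodeResult:
    """Per-frequency steady-state amplitude ratio (output/input), per population.

    All frequencies run as one batch.  Output amplitude is half the raw
    peak-to-peak of the last ``measure_ms``; a cell is flagged non-entrained
    when its dominant output frequency differs from the input frequency by
    more than one FFT bin (plus a 2% slack for spectral leakage).
    """
    freqs = np.asarray(freqs_hz, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    u1 = InputSignal.sinusoid(mean=input_mean, amplitude=input_amplitude,
                              frequency_hz=freqs)
    cfg = IntegratorConfig(dt=dt_ms, duration=settle_ms + measure_ms)
    traj = simulate(p, u1, InputSignal.constant(u2), controller=controller, cfg=cfg)

    amp1, amp2 = _steady_amplitudes(traj, measure_ms)
    ratio1 = 0.5 * amp1 / input_amplitude
    ratio2 = 0.5 * amp2 / input_amplitude

    fs = traj.fs_hz
    n_meas = int(round(measure_ms / dt_ms))
    bin_hz = fs / n_meas
    dom = np.empty(freqs.size)
    entrained = np.empty(freqs.size, dtype=bool)
    for k in range(freqs.size):
        f = dominant_frequency(traj.x1[:, k], fs, transient_ms=settle_ms)
        dom[k] = np.nan if f is None else f
        entrained[k] = f is not None and abs(f - freqs[k]) <= bin_hz + 0.02 * freqs[k]

    label = "off" if controller is None or controller.mode == "off" else controller.mode
    return BodeResult(
        freqs_hz=freqs, input_mean=float(input_mean),
        input_amplitude=float(input_amplitude),
        ratio_stn=ratio1, ratio_gpe=ratio2,
        controller=label, entrained=entrained, dominant_hz=dom,
    )


def linearized_transfer(
    p: LoopParams,
    freqs_hz,
    u1: float,
    u2: float = DEFAULT_U2,
) -> tuple[np.ndarray, np.ndarray]:
    """Transfer function of the linearization about the operating point.

    Linearizing the loop at the equilibrium for constant drive ``(u1, u2)``
    with activation slopes ``s_i`` evaluated at the equilibrium input drives,
    the response of each population to a small cortical perturbation at angular
    frequency ``w`` is::

        H1(iw) = s1 b1 / (D1 + s1 c12 e^{-iw d12} s2 c21 e^{-iw d21} / D2)
        H2(iw) = H1(iw) s2 c21 e^{-iw d21} / D2

    with ``D1 = 1 + iw tau1 - s1 c11 e^{-iw d11}`` and ``D2 = 1 + iw tau2 +
    s2 c22 e^{-iw d22}``.  Returns complex arrays ``(H1, H2)``.
    """
    eq = find_equilibrium(p, u1=u1, u2=u2)
    z1 = float(p.c11) * eq.x1 - float(p.c12) * eq.x2 + p.b1 * u1
    z2 = float(p.c21) * eq.x1 - float(p.c22) * eq.x2 - p.b2 * u2
    s1 = activation_slope(p.s1, z1)
    s2 = activation_slope(p.s2, z2)

    w = 2.0e-3 * np.pi * np.asarray(freqs_hz, dtype=float)  # rad/ms
    e11 = np.exp(-1j * w * p.d11)
    e12 = np.exp(-1j * w * p.d12)
    e21 = np.exp(-1j * w * p.d21)
    e22 = np.exp(-1j * w * p.d22)
    d1 = 1.0 + 1j * w * p.tau1 - s1 * float(p.c11) * e11
    d2 = 1.0 + 1j * w * p.tau2 + s2 * float(p.c22) * e22
    h1 = s1 * p.b1 / (d1 + s1 * float(p.c12) * e12 * s2 * float(p.c21) * e21 / d2)
    h2 = h1 * s2 * float(p.c21) * e21 / d2
    return h1, h2
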