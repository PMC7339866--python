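"""Identification of the GPe activation function and self-coupling from
steady-state rate data.

The GPe population, disconnected from everything but its STN drive, obeys

    tau2 x2'(t) = -x2(t) + S2(u(t) + c22 x2(t - d22)),

so steady states satisfy the fixed-point equation ``x = S2(u + c22 x)``.  The
procedure estimates S2 and c22 in two stages from (STN rate, GPe steady-state
rate) pairs:

1.  With the self-coupling absent (c22 = 0) the pairs sample S2 directly.  A
    linear function is fitted through the central portion of the data to read
    off an overall slope ``a``; the data divided by ``a`` is fitted with the
    unit-max-slope sigmoid ``S(x) = M B / (B + exp(-4x/M)(M - B))``; the
    activation estimate is ``a`` times that sigmoid (so its maximal slope is
    ``a``).  A joint least-squares refinement of (a, M, B), seeded by those
    two-stage values, removes the bias of the central linear fit.
2.  With the self-coupling present, the predicted steady state ``f_c22(u)``
    (the fixed point above) is compared to the data over a grid of candidate
    c22 values, minimizing the normalized squared error

        nLSQ(c22) = sum_i (f_c22(u_i) - x2_i)^2 / sum_i x2_i^2,

    ties broken toward the smaller c22.

The stabilizability condition for the closed STN-GPe loop is ``c22 * l2 < 1``
with ``l2`` the maximal slope of S2 — self-inhibition weak enough that the GPe
cannot pace itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import ActivationParams, activation, activation_max_slope

__all__ = [
    "RatePairs",
    "IdentificationResult",
    "fit_activation",
    "gpe_steady_state",
    "estimate_c22",
    "stabilizability_check",
    "generate_rate_pairs",
    "identify",
]


@dataclass(frozen=True)
class RatePairs:
    """Paired samples of STN drive rate and GPe steady-state rate (pulses/s)."""

    u: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        object.__setattr__(self, "x2", np.asarray(self.x2, dtype=float))
        if self.u.shape != self.x2.shape or self.u.ndim != 1:
            raise ValueError("u and x2 must be 1-D arrays of equal length")
        if np.any(self.u < 0) or np.any(self.x2 < 0):
            raise ValueError("rates must be non-negative")

    def __len__(self) -> int:
        return self.u.size

    @classmethod
    def from_csv(cls, path) -> "RatePairs":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(u=df.iloc[:, 0].to_numpy(), x2=df.iloc[:, 1].to_numpy())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"u": self.u, "x2": self.x2}).to_csv(path, index=False)


@dataclass(frozen=True)
class IdentificationResult:
    """Fitted activation scale/shape, estimated self-coupling and fit quality."""

    a: float
    activation: ActivationParams
    c22: float
    nlsq: float
    grid: np.ndarray = field(repr=False)
    nlsq_curve: np.ndarray = field(repr=False)

    @property
    def l2(self) -> float:
        """Maximal slope of the fitted GPe activation."""
        return activation_max_slope(self.activation)

    @property
    def stabilizable(self) -> bool:
        ok, _ = stabilizability_check(self.c22, self.l2)
        return ok

    def to_json(self, path=None) -> str:
        payload = {
            "a": self.a,
            "m": self.activation.m,
            "b": self.activation.b,
            "c22": self.c22,
            "nlsq": self.nlsq,
            "l2": self.l2,
            "stabilizable": self.stabilizable,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_activation(pairs: RatePairs, central_fraction: float = 0.5
                   ) -> tuple[float, ActivationParams]:
    """Estimate the scaled activation ``a * S_{M,B}`` from no-self-coupling pairs.

    Two-stage procedure (linear pre-fit for ``a`` on the central
    ``central_fraction`` of the drive range, then a unit-slope sigmoid fit to
    the rescaled data) followed by a joint (a, M, B) refinement initialized at
    the two-stage estimate.

    Raises ``ValueError`` on degenerate data (fewer than 4 distinct drives or
    constant response).
    """
    from scipy.optimize import curve_fit

    u, x2 = pairs.u, pairs.x2
    if np.unique(u).size < 4:
        raise ValueError("need at least 4 distinct drive values for a 3-parameter fit")
    if np.ptp(x2) <= 0:
        raise ValueError("GPe response is constant; activation not identifiable")

    lo = np.min(u) + 0.5 * (1.0 - central_fraction) * np.ptp(u)
    hi = np.max(u) - 0.5 * (1.0 - central_fraction) * np.ptp(u)
    central = (u >= lo) & (u <= hi)
    if central.sum() < 2:
        central = np.ones_like(u, dtype=bool)
    a0 = float(np.polyfit(u[central], x2[central], 1)[0])
    if not a0 > 0:
        raise ValueError("central linear fit has non-positive slope; data unfittable")

    def unit_sigmoid(x, m, b):
        return activation(ActivationParams(m=m, b=b), x)

    y = x2 / a0
    m_guess = max(1.05 * np.max(y), 1e-3)
    b_guess = min(max(np.median(y[u <= np.quantile(u, 0.2)]), 1e-3), 0.9 * m_guess)
    (m1, b1), _ = curve_fit(unit_sigmoid, u, y, p0=(m_guess, b_guess),
                            bounds=([1e-6, 1e-9], [np.inf, np.inf]), maxfev=20000)

    def scaled_sigmoid(x, a, m, b):
        return a * activation(ActivationParams(m=m, b=b), x)

    (a_fit, m_fit, b_fit), _ = curve_fit(
        scaled_sigmoid, u, x2, p0=(a0, m1, min(b1, 0.999 * m1)),
        bounds=([1e-9, 1e-6, 1e-9], [np.inf, np.inf, np.inf]), maxfev=20000,
    )
    if not b_fit < m_fit:
        raise ValueError("sigmoid fit collapsed (B >= M); data unfittable")
    return float(a_fit), ActivationParams(m=float(m_fit), b=float(b_fit),
                                          scale=float(a_fit))


def gpe_steady_state(
    s2: ActivationParams,
    c22: float,
    u,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> float | np.ndarray:
    """Fixed point of ``x = S2(u + c22 x)`` by damped iteration.

    Under the contraction condition ``c22 * l2 < 1`` the fixed point is unique
    and the damped map ``x <- (1-lam) x + lam S2(u + c22 x)`` converges; the
    solver reports ``c22 * l2`` if it fails to converge.  Vectorized over ``u``.
    """
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    x = activation(s2, u_arr)
    if c22 == 0.0:
        return float(x[0]) if np.ndim(u) == 0 else x
    for _ in range(max_iter):
        fx = activation(s2, u_arr + c22 * x)
        x_new = (1.0 - damping) * x + damping * fx
        if np.max(np.abs(fx - x)) < tol:
            x = x_new
            break
        x = x_new
    else:
        l2 = activation_max_slope(s2)
        raise RuntimeError(
            f"fixed-point iteration did not converge; c22 * l2 = {c22 * l2:.3f} "
            "(contraction requires < 1)"
        )
    return float(x[0]) if np.ndim(u) == 0 else x


def estimate_c22(
    s2: ActivationParams,
    pairs: RatePairs,
    grid=None,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Grid search for the self-coupling minimizing the normalized squared error.

    Returns ``(c22_hat, nlsq_min, grid, nlsq_curve)``.  The default grid is
    0 : 0.01 : 0.9 / l2 (inside the contraction region); ties break toward the
    smaller candidate.
    """
    if grid is None:
        l2 = activation_max_slope(s2)
        grid = np.arange(0.0, 0.9 / l2 + 1e-12, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("candidate grid for c22 is empty")
    denom = float(np.sum(pairs.x2 ** 2))
    if denom == 0:
        raise ValueError("all-zero GPe rates; nLSQ undefined")
    curve = np.empty(grid.size)
    for k, c in enumerate(grid):
        pred = gpe_steady_state(s2, float(c), pairs.u)
        curve[k] = float(np.sum((pred - pairs.x2) ** 2) / denom)
    k_best = int(np.argmin(curve))  # argmin returns the first (smallest) on ties
    return float(grid[k_best]), float(curve[k_best]), grid, curve


def stabilizability_check(c22: float, l2: float) -> tuple[bool, float]:
    """Check ``c22 * l2 < 1``; returns (satisfied, margin = 1 - c22*l2)."""
    if c22 < 0 or l2 < 0:
        raise ValueError("c22 and l2 must be non-negative")
    margin = 1.0 - c22 * l2
    return margin > 0.0, float(margin)


def generate_rate_pairs(
    s2: ActivationParams,
    c22: float,
    n: int,
    rng: np.random.Generator,
    u_range: tuple[float, float] | None = None,
    noise: float = 0.0,
) -> RatePairs:
    """Synthetic (drive, steady-state) pairs from a known activation and c22.

    Drives are uniform over the activation's dynamic range (default: inflection
    point +/- M, covering baseline through saturation); multiplicative Gaussian
    noise of relative s.d. ``noise`` is applied to the responses.
    """
    if u_range is None:
        x_inf = 0.25 * s2.m * np.log((s2.m - s2.b) / s2.b)
        u_range = (x_inf - s2.m, x_inf + s2.m)
    u = rng.uniform(u_range[0], u_range[1], size=n)
    u = np.clip(np.sort(u), 0.0, None)
    x2 = np.asarray(gpe_steady_state(s2, c22, u))
    if noise > 0:
        x2 = x2 * (1.0 + noise * rng.standard_normal(n))
        x2 = np.clip(x2, 0.0, None)
    return RatePairs(u=u, x2=x2)


def identify(
    pairs_open: RatePairs,
    pairs_coupled: RatePairs,
    grid=None,
) -> IdentificationResult:
    """Full identification: activation from open pairs, c22 from coupled pairs."""
    a, act = fit_activation(pairs_open)
    c22, nlsq, grid_out, curve = estimate_c22(act, pairs_coupled, grid=grid)
    return IdentificationResult(a=a, activation=act, c22=c22, nlsq=nlsq,
                                grid=grid_out, nlsq_curve=curve)
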