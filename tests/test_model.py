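"""Activation identities, equilibria (dual-route), and simulation invariants
of the STN-GPe firing-rate loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stngpe import (
    ActivationParams,
    InputSignal,
    IntegratorConfig,
    LoopParams,
    activation,
    activation_max_slope,
    activation_slope,
    find_equilibrium,
    shift_activation,
    simulate,
)
from stngpe.model import GPE_ACTIVATION, STN_ACTIVATION, activation as act


class TestActivation:
    @pytest.mark.parametrize("params,expected", [
        (STN_ACTIVATION, 17.0),   # S(0) = M*B/(B + (M-B)) = B
        (GPE_ACTIVATION, 75.0),
    ])
    def test_value_at_zero_is_baseline(self, params, expected):
        assert activation(params, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_saturation_limits(self):
        assert activation(STN_ACTIVATION, 1e6) == pytest.approx(300.0, rel=1e-9)
        assert activation(STN_ACTIVATION, -1e6) == pytest.approx(0.0, abs=1e-9)

    def test_overflow_safe(self):
        assert np.isfinite(activation(STN_ACTIVATION, -1e300))
        assert np.isfinite(activation(STN_ACTIVATION, 1e300))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        m=st.floats(1.0, 500.0),
        frac=st.floats(0.01, 0.99),
        scale=st.floats(0.1, 3.0),
        xfrac=st.floats(-3.0, 3.0),   # drive relative to the dynamic range M
        dxfrac=st.floats(1e-3, 1.0),
    )
    def test_strictly_increasing_and_bounded(self, m, frac, scale, xfrac, dxfrac):
        p = ActivationParams(m=m, b=frac * m, scale=scale)
        lo, hi = activation(p, xfrac * m), activation(p, (xfrac + dxfrac) * m)
        assert 0.0 < lo < hi < p.max_rate + 1e-12

    def test_analytic_slope_matches_finite_difference(self):
        p = GPE_ACTIVATION
        xs = np.linspace(-200, 300, 7)
        h = 1e-5
        fd = (act(p, xs + h) - act(p, xs - h)) / (2 * h)
        assert np.allclose(activation_slope(p, xs), fd, rtol=1e-6, atol=1e-9)


class TestMaxSlope:
    def test_unit_scale_gives_unit_slope(self):
        for p in (STN_ACTIVATION, GPE_ACTIVATION, ActivationParams(m=120.0, b=5.0)):
            assert activation_max_slope(p) == pytest.approx(1.0, abs=1e-4)

    def test_rescaled_gpe_slope(self):
        p = ActivationParams(m=400.0, b=75.0, scale=1.29)
        assert activation_max_slope(p) == pytest.approx(1.29, abs=2e-4)

    def test_scale_linearity(self):
        base = activation_max_slope(ActivationParams(m=300.0, b=17.0))
        scaled = activation_max_slope(ActivationParams(m=300.0, b=17.0, scale=2.5))
        assert scaled == pytest.approx(2.5 * base, rel=1e-6)


class TestShiftedActivation:
    def test_zero_offset(self):
        f = shift_activation(STN_ACTIVATION, 0.0)
        assert f(0.0) == 0.0
        assert f(10.0) == pytest.approx(activation(STN_ACTIVATION, 10.0) - 17.0)

    def test_zero_at_origin_and_monotone(self):
        f = shift_activation(GPE_ACTIVATION, 42.0)
        assert f(0.0) == 0.0
        ys = f(np.linspace(-100, 100, 201))
        assert np.all(np.diff(ys) > 0)

    def test_max_slope_preserved(self):
        f = shift_activation(GPE_ACTIVATION, 37.0)
        xs = np.linspace(-600, 600, 100001)
        slope = np.max(np.diff(f(xs)) / np.diff(xs))
        assert slope == pytest.approx(activation_max_slope(GPE_ACTIVATION), abs=1e-4)


class TestEquilibrium:
    def test_decoupled_fixed_point_is_baseline(self):
        p = LoopParams(c12=0.0, c21=0.0, c22=0.0, b1=0.0, b2=0.0)
        eq = find_equilibrium(p, u1=5.0, u2=3.0)
        assert eq.x1 == pytest.approx(17.0, abs=1e-9)
        assert eq.x2 == pytest.approx(75.0, abs=1e-9)

    def test_shifted_system_equilibrium_at_origin(self):
        p = LoopParams.endogenous()
        eq = find_equilibrium(p, u1=27.0)
        f1 = shift_activation(p.s1, -p.c12 * eq.x2 + p.b1 * 27.0)
        f2 = shift_activation(p.s2, p.c21 * eq.x1 - p.c22 * eq.x2 - p.b2 * 2.0)
        # at zero deviation both shifted activations return zero: origin is fixed
        assert f1(0.0) == 0.0 and f2(0.0) == 0.0

    def test_against_damped_iteration_oracle(self, endogenous):
        eq = find_equilibrium(endogenous, u1=27.0)
        assert eq.residual < 1e-10
        p, lam = endogenous, 0.1
        x = np.array([50.0, 50.0])
        for _ in range(200_000):
            f = np.array([
                activation(p.s1, -p.c12 * x[1] + p.b1 * 27.0),
                activation(p.s2, p.c21 * x[0] - p.c22 * x[1] - p.b2 * 2.0),
            ])
            x_new = (1 - lam) * x + lam * f
            if np.max(np.abs(x_new - x)) < 1e-13:
                break
            x = x_new
        assert x[0] == pytest.approx(eq.x1, abs=1e-9)
        assert x[1] == pytest.approx(eq.x2, abs=1e-9)


class TestSimulate:
    def test_equilibrium_invariance(self, endogenous):
        """Resting exactly at the fixed point, the loop stays there for 1 s."""
        cfg = IntegratorConfig(dt=0.1, duration=1000.0)
        traj = simulate(endogenous, InputSignal.constant(27.0), cfg=cfg)
        eq = find_equilibrium(endogenous, u1=27.0)
        assert np.max(np.abs(traj.x1 - eq.x1)) < 1e-9
        assert np.max(np.abs(traj.x2 - eq.x2)) < 1e-9

    def test_zero_couplings_constant_trajectory(self):
        p = LoopParams(c12=0.0, c21=0.0, c22=0.0, b1=1.0, b2=1.0)
        cfg = IntegratorConfig(dt=0.1, duration=300.0)
        traj = simulate(p, InputSignal.constant(4.0), cfg=cfg)
        assert np.ptp(traj.x1) < 1e-9 and np.ptp(traj.x2) < 1e-9

    def test_rates_stay_in_physical_bounds(self, endogenous):
        cfg = IntegratorConfig(dt=0.1, duration=1500.0)
        traj = simulate(endogenous, InputSignal.constant(27.0), cfg=cfg,
                        perturb=10.0)
        assert traj.x1.min() >= -1e-9
        assert traj.x1.max() <= endogenous.s1.max_rate + 1e-9
        assert traj.x2.min() >= -1e-9
        assert traj.x2.max() <= endogenous.s2.max_rate + 1e-9
        # and the strong-coupling loop actually oscillates
        assert np.ptp(traj.x1[-5000:]) > 1.0

    def test_entrainment_at_input_frequency(self, exogenous):
        """In the stable regime a sinusoidal drive entrains both populations."""
        from stngpe import dominant_frequency

        freqs = np.array([10.0, 20.0, 30.0])
        u1 = InputSignal.sinusoid(mean=50.0, amplitude=10.0, frequency_hz=freqs)
        cfg = IntegratorConfig(dt=0.1, duration=3000.0)
        traj = simulate(exogenous, u1, cfg=cfg)
        bin_hz = traj.fs_hz / (traj.t_ms.size - 10_000)
        for k, f in enumerate(freqs):
            got = dominant_frequency(traj.x1[:, k], traj.fs_hz, transient_ms=1000.0)
            assert got == pytest.approx(f, abs=bin_hz + 1e-9)

    def test_trajectory_csv_round_trip(self, exogenous, tmp_path):
        import pandas as pd

        cfg = IntegratorConfig(dt=0.1, duration=50.0)
        traj = simulate(exogenous, InputSignal.constant(50.0), cfg=cfg)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["t_ms", "x1", "x2", "theta", "mu", "u1", "u2"]
        assert np.allclose(df["x1"].to_numpy(), traj.x1[:, 0])


class TestInputSignal:
    def test_step_switches_level(self):
        u = InputSignal.step([27.0, 42.0], [750.0])
        assert u.value(0.0) == 27.0
        assert u.value(749.9) == 27.0
        assert u.value(750.0) == 42.0

    def test_sinusoid_with_segment_switch(self):
        u = InputSignal.sinusoid(mean=[50.0, 60.0], amplitude=[10.0, 60.0],
                                 frequency_hz=20.0, switch_times_ms=[750.0])
        # 20 Hz: period 50 ms, so t=700 and t=800 are at phase zero
        assert u.value(700.0) == pytest.approx(50.0, abs=1e-9)
        assert u.value(800.0) == pytest.approx(60.0, abs=1e-9)

    def test_sampled_interpolates_and_checks_span(self):
        u = InputSignal(kind="sampled", samples=np.array([0.0, 2.0, 4.0]),
                        sample_dt_ms=1.0)
        assert u.value(0.5) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            u.value(5.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ActivationParams(m=10.0, b=20.0)
        with pytest.raises(ValueError):
            LoopParams(c12=-1.0, c21=0.0, c22=0.0, b1=0.0, b2=0.0)
        with pytest.raises(ValueError):
            InputSignal(kind="triangle")
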