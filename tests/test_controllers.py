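"""Control laws: output conventions, exact gain-update forms, biomarker
drives, the analytic gain bound, and closed-loop gain behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stngpe import (
    ControllerConfig,
    InputSignal,
    IntegratorConfig,
    adaptive_gain_step,
    beta_drive,
    controller_output,
    error_drive,
    simulate,
    theta_star_bound,
)


class TestControllerOutput:
    def test_proportional_negative_feedback(self):
        cfg = ControllerConfig(mode="proportional", theta=2.0)
        assert controller_output(cfg, 2.0, 5.0) == -10.0

    def test_zero_gain_silences(self):
        cfg = ControllerConfig(mode="adaptive_abs")
        assert controller_output(cfg, 0.0, 123.0) == 0.0

    def test_arv_mode_positive_feedback(self):
        cfg = ControllerConfig(mode="adaptive_arv")
        assert controller_output(cfg, 25.0, 1.0) == 25.0

    def test_off_mode(self):
        cfg = ControllerConfig(mode="off")
        assert controller_output(cfg, 7.0, 3.0) == 0.0


class TestAdaptiveGainStep:
    def test_zero_drive_exponential_decay(self):
        """theta(t) = exp(-sigma t / tau); halves every tau/sigma * ln 2."""
        sigma, tau, dt = 0.1, 50.0, 0.1
        theta = 1.0
        n = 10_000  # 1 s
        for _ in range(n):
            theta = adaptive_gain_step(theta, 0.0, sigma, tau, dt)
        t = n * dt
        assert theta == pytest.approx(np.exp(-sigma * t / tau), abs=1e-9)
        half_life = tau / sigma * np.log(2.0)
        assert half_life == pytest.approx(346.57, abs=0.01)

    def test_constant_drive_converges_to_ratio(self):
        sigma, tau, dt, d = 0.2, 50.0, 0.5, 0.8
        theta = 0.0
        for _ in range(20_000):
            theta = adaptive_gain_step(theta, d, sigma, tau, dt)
        assert theta == pytest.approx(d / sigma, rel=1e-9)

    def test_matches_linear_ode_solution_along_the_way(self):
        sigma, tau, dt, d, theta0 = 0.1, 50.0, 0.1, 0.3, 1.0
        theta = theta0
        for k in range(1, 5001):
            theta = adaptive_gain_step(theta, d, sigma, tau, dt)
            t = k * dt
            exact = d / sigma + (theta0 - d / sigma) * np.exp(-sigma * t / tau)
            assert abs(theta - exact) < 1e-6

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(theta=st.floats(0.0, 100.0), drive=st.floats(0.0, 50.0),
           sigma=st.floats(0.0, 1.0), tau=st.floats(1.0, 500.0))
    def test_gain_stays_nonnegative(self, theta, drive, sigma, tau):
        assert adaptive_gain_step(theta, drive, sigma, tau, 0.1) >= 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(theta=st.floats(0.0, 100.0), drive=st.floats(0.0, 50.0),
           tau=st.floats(1.0, 500.0))
    def test_sigma_zero_never_decreases(self, theta, drive, tau):
        assert adaptive_gain_step(theta, drive, 0.0, tau, 0.1) >= theta


class TestBetaDrive:
    fs = 10_000.0

    def test_zero_signal(self):
        assert beta_drive(np.zeros(8000), self.fs) == 0.0

    def test_in_band_sinusoid_returns_peak_to_peak(self):
        """20 Hz sinusoid of amplitude A: drive ~ 2A * |H(20 Hz)| within 10%."""
        from scipy.signal import sosfreqz

        from stngpe.signal_metrics import FilterSpec, design_sos

        a = 3.0
        t = np.arange(int(1.5 * self.fs)) / self.fs
        x = a * np.sin(2 * np.pi * 20.0 * t)
        drive = beta_drive(x, self.fs)
        sos = design_sos(FilterSpec.beta_butter(self.fs))
        _, h = sosfreqz(sos, worN=[20.0], fs=self.fs)
        expected = 2.0 * a * np.abs(h[0])
        assert drive == pytest.approx(expected, rel=0.10)

    def test_out_of_band_sinusoid_attenuated(self):
        a = 3.0
        t = np.arange(int(1.5 * self.fs)) / self.fs
        x = a * np.sin(2 * np.pi * 50.0 * t)
        assert beta_drive(x, self.fs) < 0.1 * 2.0 * a

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            beta_drive(np.zeros(100), self.fs)


class TestErrorDrive:
    @pytest.mark.parametrize("biomarker,target,expected", [
        (0.2, 0.1, 0.1),
        (0.05, 0.1, 0.0),   # below target: half-wave rectified to zero
        (0.1, 0.1, 0.0),
    ])
    def test_half_wave_rectification(self, biomarker, target, expected):
        assert error_drive(biomarker, target) == pytest.approx(expected)

    def test_normalized_variant(self):
        assert error_drive(0.2, 0.1, normalize=True) == pytest.approx(1.0)
        assert error_drive(0.05, 0.1, normalize=True) == 0.0


class TestThetaStarBound:
    def test_zero_couplings(self):
        assert theta_star_bound(0.0, 0.0, 5.0, 0.5).theta_star == 0.0

    def test_printed_formula_arithmetic(self):
        # 8 * (4 * 10^2 * 3^2 / (1 - 0.9)^2) with no self-excitation
        got = theta_star_bound(0.0, 3.0, 10.0, 0.9).theta_star
        assert got == pytest.approx(2_880_000.0, rel=1e-12)

    def test_diverges_toward_unit_self_coupling(self):
        vals = [theta_star_bound(0.0, 3.0, 10.0, c).theta_star
                for c in (0.5, 0.9, 0.99, 0.999)]
        assert np.all(np.diff(vals) > 0)
        with pytest.raises(ValueError):
            theta_star_bound(0.0, 3.0, 10.0, 1.0)


class TestClosedLoopGain:
    def test_gain_nonnegative_throughout(self, endogenous):
        cfg = IntegratorConfig(dt=0.1, duration=1500.0)
        ctrl = ControllerConfig(mode="adaptive_beta", tau_theta_ms=75.0,
                                sigma=0.19, t_on_ms=200.0)
        traj = simulate(endogenous, InputSignal.constant(27.0),
                        controller=ctrl, cfg=cfg, perturb=5.0)
        assert traj.theta.min() >= 0.0

    def test_zero_beta_content_shuts_gain_down(self, exogenous):
        """Constant input, stable loop: no beta drive, so theta leaks to ~0."""
        cfg = IntegratorConfig(dt=0.1, duration=2500.0)
        ctrl = ControllerConfig(mode="adaptive_beta", theta0=1.0,
                                tau_theta_ms=50.0, sigma=0.1)
        traj = simulate(exogenous, InputSignal.constant(50.0),
                        controller=ctrl, cfg=cfg)
        # after 5 leak time constants theta is far below 1% of theta0
        assert traj.theta[-1, 0] < 0.01
        assert np.all(np.diff(traj.theta[:, 0]) <= 1e-12)

    def test_adaptive_arv_mode_rejected_for_rate_model(self, exogenous):
        cfg = IntegratorConfig(dt=0.1, duration=10.0)
        ctrl = ControllerConfig(mode="adaptive_arv")
        with pytest.raises(ValueError, match="plant-facing"):
            simulate(exogenous, InputSignal.constant(50.0), controller=ctrl,
                     cfg=cfg)

    def test_invalid_controller_configs_rejected(self):
        with pytest.raises(ValueError):
            ControllerConfig(mode="bangbang")
        with pytest.raises(ValueError):
            ControllerConfig(mode="adaptive_abs", sigma=-0.1)
        with pytest.raises(ValueError):
            ControllerConfig(mode="adaptive_abs", tau_theta_ms=0.0)
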