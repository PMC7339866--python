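"""Activation-function and self-coupling identification: parameter recovery,
fixed-point consistency with dynamic simulation, and estimator behavior."""

import numpy as np
import pytest

from stngpe import ActivationParams, activation, activation_max_slope
from stngpe.identification import (
    RatePairs,
    estimate_c22,
    fit_activation,
    generate_rate_pairs,
    gpe_steady_state,
    identify,
    stabilizability_check,
)

TRUTH = ActivationParams(m=400.0, b=75.0, scale=1.29)


class TestFitActivation:
    def test_noiseless_recovery_within_one_percent(self, rng):
        pairs = generate_rate_pairs(TRUTH, 0.0, 60, rng)
        a, act = fit_activation(pairs)
        assert a == pytest.approx(1.29, rel=0.01)
        assert act.m == pytest.approx(400.0, rel=0.01)
        assert act.b == pytest.approx(75.0, rel=0.01)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(7)
        pairs = generate_rate_pairs(TRUTH, 0.0, 50, rng, noise=0.05)
        a, act = fit_activation(pairs)
        assert a == pytest.approx(1.29, rel=0.10)
        assert act.m == pytest.approx(400.0, rel=0.10)
        assert act.b == pytest.approx(75.0, rel=0.10)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            fit_activation(RatePairs(u=np.zeros(10), x2=np.linspace(1, 10, 10)))
        with pytest.raises(ValueError):
            fit_activation(RatePairs(u=np.linspace(0, 100, 10),
                                     x2=np.full(10, 5.0)))


class TestGpeSteadyState:
    def test_no_self_coupling_is_plain_activation(self):
        assert gpe_steady_state(TRUTH, 0.0, 42.0) == pytest.approx(
            activation(TRUTH, 42.0))

    def test_matches_dynamic_simulation(self):
        """Fixed point agrees with the long-run delayed rate equation."""
        from stngpe.dde_core import IntegratorConfig, integrate_dde

        c22, u = 0.35, 100.0
        fp = gpe_steady_state(TRUTH, c22, u)

        def rhs(t, y, lag):
            return (-y + activation(TRUTH, u + c22 * lag[0])) / 14.0

        sol = integrate_dde(rhs, [4.0], np.array([activation(TRUTH, u)]),
                            IntegratorConfig(dt=0.1, duration=500.0))
        assert sol.y[-1, 0] == pytest.approx(fp, abs=1e-6)

    def test_saturates_at_sup(self):
        assert gpe_steady_state(TRUTH, 0.3, 1e5) == pytest.approx(
            TRUTH.max_rate, rel=1e-6)

    def test_monotone_in_drive_and_coupling(self):
        us = np.linspace(0, 300, 30)
        x_lo = gpe_steady_state(TRUTH, 0.1, us)
        x_hi = gpe_steady_state(TRUTH, 0.5, us)
        assert np.all(np.diff(x_lo) >= 0)
        assert np.all(x_hi >= x_lo)


class TestEstimateC22:
    def test_recovers_printed_value_noiseless(self, rng):
        pairs = generate_rate_pairs(TRUTH, 0.35, 60, rng)
        c22, nlsq, _, _ = estimate_c22(TRUTH, pairs)
        assert c22 == pytest.approx(0.35, abs=1e-9)
        assert nlsq < 1e-12

    def test_zero_coupling_recovered(self, rng):
        pairs = generate_rate_pairs(TRUTH, 0.0, 40, rng)
        c22, nlsq, _, _ = estimate_c22(TRUTH, pairs)
        assert c22 == 0.0
        assert nlsq < 1e-12

    def test_estimate_minimizes_curve(self, rng):
        pairs = generate_rate_pairs(TRUTH, 0.2, 40, rng, noise=0.05)
        c22, nlsq, grid, curve = estimate_c22(TRUTH, pairs)
        assert nlsq == curve.min()
        assert np.all(nlsq <= curve)

    def test_empty_grid_rejected(self, rng):
        pairs = generate_rate_pairs(TRUTH, 0.2, 10, rng)
        with pytest.raises(ValueError):
            estimate_c22(TRUTH, pairs, grid=[])

    def test_rmse_shrinks_with_sample_size(self):
        """Recovery error over noisy replicates decreases as n grows."""
        sizes = [10, 25, 50, 100]
        rmse = []
        for n in sizes:
            errs = []
            for rep in range(40):
                rng = np.random.default_rng(1000 + rep)
                pairs = generate_rate_pairs(TRUTH, 0.35, n, rng, noise=0.05)
                c22, _, _, _ = estimate_c22(TRUTH, pairs)
                errs.append(c22 - 0.35)
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmse[-1] < rmse[0]
        assert np.all(np.diff(rmse) <= 0.01)  # monotone up to grid granularity


class TestStabilizability:
    def test_identified_values_satisfy_criterion(self):
        ok, margin = stabilizability_check(0.35, 1.29)
        assert ok
        assert margin == pytest.approx(0.5485, abs=1e-4)

    def test_boundary_excluded(self):
        ok, margin = stabilizability_check(1.0, 1.0)
        assert not ok and margin == 0.0

    def test_zero_coupling_always_ok(self):
        assert stabilizability_check(0.0, 123.0)[0]


class TestEndToEnd:
    def test_identify_pipeline_and_json(self, rng, tmp_path):
        open_pairs = generate_rate_pairs(TRUTH, 0.0, 60, rng)
        coupled = generate_rate_pairs(TRUTH, 0.35, 60, rng)
        res = identify(open_pairs, coupled)
        assert res.c22 == pytest.approx(0.35, abs=1e-9)
        assert res.l2 == pytest.approx(1.29, rel=0.01)
        assert res.stabilizable
        path = tmp_path / "ident.json"
        res.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["c22"] == pytest.approx(0.35)

    def test_rate_pairs_csv_round_trip(self, rng, tmp_path):
        pairs = generate_rate_pairs(TRUTH, 0.1, 20, rng)
        path = tmp_path / "pairs.csv"
        pairs.to_csv(path)
        back = RatePairs.from_csv(path)
        assert np.allclose(back.u, pairs.u)
        assert np.allclose(back.x2, pairs.x2)
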