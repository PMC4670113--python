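"""Euler-Maruyama integrator, reproducibility and OU validation."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from mesowm import (
    SimulationSettings,
    em_step,
    force,
    jacobian,
    ou_stationary_covariance,
    simulate_ensemble,
    simulate_linear_ensemble,
    burn_in_diagnostic,
)
from mesowm.params import paper_defaults


def noiseless(params):
    return replace(params, sigma1=0.0, sigma2=0.0, sigma3=0.0, sigma4=0.0)


class TestEmStep:
    def test_zero_noise_is_explicit_euler(self, params, rng):
        p = noiseless(params)
        x = rng.uniform(0.1, 2.0, size=4)
        z = rng.standard_normal(4)
        expected = x + force(x, p) * 0.001
        np.testing.assert_allclose(em_step(x, p, 0.001, z), expected, rtol=1e-14)

    def test_origin_with_zero_draws_stays(self, params):
        out = em_step(np.zeros(4), params, 0.001, np.zeros(4))
        np.testing.assert_array_equal(out, np.zeros(4))

    def test_unit_draw_displacement_from_origin(self, params):
        """One step from the origin with unit draws is sigma_i * sqrt(dt)."""
        dt = 0.001
        out = em_step(np.zeros(4), params, dt, np.ones(4))
        np.testing.assert_allclose(out, params.sigmas * np.sqrt(dt), rtol=1e-14)

    def test_rejects_bad_dt(self, params):
        with pytest.raises(ValueError):
            em_step(np.zeros(4), params, 0.0, np.zeros(4))


class TestEnsemble:
    def test_seed_determinism(self, params, bistable_fixed_points):
        s = SimulationSettings(dt=0.01, n_steps=200, n_realizations=50, seed=42)
        x0 = bistable_fixed_points[1].state
        a = simulate_ensemble(x0, params, s)
        b = simulate_ensemble(x0, params, s)
        np.testing.assert_array_equal(a.final_states, b.final_states)
        c = simulate_ensemble(x0, params, s.scaled(seed=43))
        assert np.any(c.final_states != a.final_states)

    def test_zero_noise_converges_to_attractor(self, params, bistable_fixed_points):
        """Deterministic EM from a perturbed stable point relaxes onto it."""
        p = noiseless(params)
        upper = bistable_fixed_points[-1].state
        # horizon >> tau4 = 800 so the slow dopamine mode fully relaxes
        s = SimulationSettings(dt=0.01, n_steps=800_000, n_realizations=1, seed=0)
        res = simulate_ensemble(upper * 1.02, p, s)
        np.testing.assert_allclose(res.final_states[0], upper, atol=1e-6)

    def test_zero_noise_matches_adaptive_integrator(self, params):
        """EM with sigma = 0 tracks solve_ivp within first-order error."""
        p = noiseless(params)
        x0 = np.array([0.5, 0.2, 0.02, 1.0])
        T = 50.0
        dt = 0.01
        s = SimulationSettings(dt=dt, n_steps=int(T / dt), n_realizations=1, seed=0)
        res = simulate_ensemble(x0, p, s)
        sol = solve_ivp(lambda t, x: force(x, p), (0, T), x0,
                        rtol=1e-10, atol=1e-12)
        err = np.max(np.abs(res.final_states[0] - sol.y[:, -1]))
        assert err < 5 * dt  # O(dt) global error with a modest constant

    def test_generic_kernel_agrees_with_default(self, params, bistable_fixed_points):
        """The recording kernel and the fast kernel share the RNG contract."""
        x0 = bistable_fixed_points[1].state
        s = SimulationSettings(dt=0.01, n_steps=100, n_realizations=20, seed=7)
        a = simulate_ensemble(x0, params, s)
        b = simulate_ensemble(x0, params, s.scaled(record_every=50))
        np.testing.assert_allclose(a.final_states, b.final_states, rtol=1e-12)
        assert b.trajectories.shape == (20, 2, 4)
        np.testing.assert_allclose(b.trajectories[:, -1], b.final_states)

    def test_burn_in_diagnostic(self, params, bistable_fixed_points):
        x0 = bistable_fixed_points[1].state
        s = SimulationSettings(dt=0.01, n_steps=1000, n_realizations=50,
                               seed=3, record_every=100)
        res = simulate_ensemble(x0, params, s)
        drift = burn_in_diagnostic(res)
        assert drift.shape == (4,)
        assert np.all(np.isfinite(drift))


class TestOUValidation:
    def test_1d_closed_form(self):
        tau, sigma = 5.0, 0.3
        S = ou_stationary_covariance(np.array([[-1.0 / tau]]), np.array([sigma]))
        assert S[0, 0] == pytest.approx(sigma ** 2 * tau / 2, rel=1e-12)

    def test_diagonal_decoupled_channels(self):
        taus = np.array([2.0, 5.0, 10.0, 800.0])
        sig = np.array([0.05, 0.01, 0.001, 0.05])
        S = ou_stationary_covariance(np.diag(-1.0 / taus), sig)
        np.testing.assert_allclose(np.diag(S), sig ** 2 * taus / 2, rtol=1e-12)
        off = S - np.diag(np.diag(S))
        assert np.max(np.abs(off)) < 1e-15

    def test_refuses_unstable_drift(self):
        with pytest.raises(ValueError):
            ou_stationary_covariance(np.array([[0.1]]), np.array([1.0]))

    def test_ensemble_matches_lyapunov_1d(self):
        """Simulated OU variance within 3 MC standard errors of sigma^2 tau/2."""
        tau, sigma = 2.0, 0.5
        A = np.array([[-1.0 / tau]])
        s = SimulationSettings(dt=0.005, n_steps=4000, n_realizations=4000, seed=11)
        X = simulate_linear_ensemble(A, np.zeros(1), np.array([sigma]), s)
        var = X[:, 0].var()
        target = sigma ** 2 * tau / 2
        se = target * np.sqrt(2.0 / s.n_realizations)
        bias = target * s.dt / (2 * tau)  # EM stationary-variance bias
        assert abs(var - target) < 3 * se + bias


class TestNoiseContract:
    def test_increment_independence(self, params):
        """Per-step noise increments of the four channels are uncorrelated."""
        x0 = np.array([0.5, 0.2, 0.02, 1.0])
        s = SimulationSettings(dt=0.01, n_steps=400, n_realizations=200,
                               seed=5, record_every=1)
        res = simulate_ensemble(x0, params, s)
        # recover increments minus drift along each trajectory
        traj = np.concatenate([np.tile(x0, (200, 1, 1)), res.trajectories], axis=1)
        inc = np.diff(traj, axis=1)  # (N, n_steps, 4)
        drift = np.stack([force(traj[:, k, :], params) * s.dt
                          for k in range(s.n_steps)], axis=1)
        noise = (inc - drift).reshape(-1, 4)
        corr = np.corrcoef(noise.T)
        off = corr - np.eye(4)
        assert np.max(np.abs(off)) < 0.02

    def test_weak_convergence_halving_dt(self, params, bistable_fixed_points):
        """Halving dt moves the ensemble mean of x1 by O(dt)."""
        x0 = bistable_fixed_points[1].state
        T = 20.0
        means = {}
        for dt in (0.08, 0.04):
            s = SimulationSettings(dt=dt, n_steps=int(T / dt),
                                   n_realizations=3000, seed=17)
            res = simulate_ensemble(x0, params, s)
            means[dt] = res.final_states[:, 0].mean()
        # first-order weak error: difference between dt and dt/2 runs is small
        assert abs(means[0.08] - means[0.04]) < 0.05
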