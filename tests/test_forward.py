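"""Forward-model layers: neural flow, balloon hemodynamics, behavior readout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from bdcm.design import InputStreams, build_input_streams, generate_task_design
from bdcm.forward import (
    hemodynamic_derivative,
    hemodynamic_observe,
    integrate,
    neural_derivative,
    response_evolve,
    rt_observe,
    rt_read_bins,
)
from bdcm.network import BDCMParams, HemodynamicParams, default_posner_structure


def toy_params(structure, **kwargs):
    p = BDCMParams.zeros(structure)
    for key, val in kwargs.items():
        setattr(p, key, val)
    return p


def impulse_streams(dt, n_bins, onset_bins, invalid=None, n_streams=2):
    u = np.zeros((n_streams, n_bins))
    onset_bins = np.asarray(onset_bins)
    u[0, onset_bins] = 1.0
    if invalid is not None:
        u[1, onset_bins] = np.asarray(invalid, dtype=float)
    return InputStreams(
        dt_s=dt, u=u, centered=False, onset_bins=onset_bins,
        names=("u1", "u2", "u3")[:n_streams],
    )


class TestNeuralDerivative:
    def test_input_free_flow_is_Ax(self, two_region, rng):
        structure, params = two_region
        x = rng.normal(size=2)
        np.testing.assert_allclose(
            neural_derivative(x, np.zeros(2), params), params.A @ x
        )

    def test_rest_flow_is_Cu(self, two_region):
        structure, params = two_region
        u = np.array([1.0, 0.0])
        np.testing.assert_allclose(
            neural_derivative(np.zeros(2), u, params), params.C @ u
        )

    def test_hand_euler_step_on_two_region_toy(self):
        structure = default_posner_structure(("A-L", "A-R"), ("A-L",))
        p = toy_params(structure)
        p.A[:] = [[-1.0, 0.0], [0.5, -1.0]]
        p.C[:, 0] = [1.0, 0.0]
        u = np.array([1.0, 0.0])
        dx = neural_derivative(np.zeros(2), u, p)
        np.testing.assert_allclose(dx, [1.0, 0.0])
        x1 = np.zeros(2) + 0.1 * dx
        np.testing.assert_allclose(x1, [0.1, 0.0])

    def test_superposition_without_modulation(self, rng):
        """With B = 0 the neural layer obeys superposition of inputs."""
        structure = default_posner_structure(("A-L", "A-R"), ("A-L",))
        p = toy_params(structure)
        p.A[:] = [[-0.5, 0.2], [0.3, -0.5]]
        p.C[:, 0] = [0.8, 0.4]
        dt, n = 0.1, 400
        resp = {}
        for name, bins in {"a": [20], "b": [120], "ab": [20, 120]}.items():
            streams = impulse_streams(dt, n, bins)
            traj = integrate(None, p, streams, np.arange(0, n, 10))
            resp[name] = traj.x
        np.testing.assert_allclose(
            resp["ab"], resp["a"] + resp["b"], atol=1e-8
        )


class TestRtObserve:
    def test_upper_bound_at_large_response_state(self):
        assert rt_observe(1e6, 0.0) == 3.0
        assert rt_observe(np.inf, 0.0) == 3.0

    def test_midpoint_at_negated_bias(self):
        for rho in (-0.3, 0.0, 0.2):
            assert rt_observe(-rho, rho) == pytest.approx(1.5)

    def test_hand_value(self):
        # 3 / (1 + e^{-1})
        assert rt_observe(0.01, 0.0) == pytest.approx(3 / (1 + np.exp(-1)))
        assert rt_observe(0.01, 0.0) == pytest.approx(2.19318, abs=1e-5)

    @given(
        r=st.floats(-1e12, 1e12, allow_nan=False),
        rho=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_readout_always_within_bounds(self, r, rho):
        s = float(rt_observe(r, rho))
        assert 0.0 <= s <= 3.0
        if abs(r + rho) < 0.05:
            assert 0.0 < s < 3.0


class TestResponseEvolve:
    def test_pure_decay_without_drive(self, two_region):
        _, params = two_region
        r_next = response_evolve(0.8, np.zeros(2), np.zeros(2), params)
        assert r_next == pytest.approx(-params.decay * 0.8)

    def test_external_gating_through_cr(self):
        structure = default_posner_structure(("A-L", "A-R"), ("A-L",), n_inputs=3)
        p = toy_params(structure)
        p.cr[:] = [0.0, 0.0, 1.0]
        g_t = 0.62
        r_next = response_evolve(0.0, np.ones(2), np.array([0, 0, g_t]), p)
        assert r_next == pytest.approx(g_t)

    def test_constant_drive_converges_to_fixed_point(self, two_region):
        _, params = two_region
        x = np.array([0.3, -0.1])
        u = np.array([0.5, 0.0])
        r = 0.0
        for _ in range(200):
            r = response_evolve(r, x, u, params)
        h = params.ar @ x + u[1] * (params.br[1] @ x) + params.cr @ u
        assert r == pytest.approx(h / (1 + params.decay), abs=1e-10)


class TestHemodynamics:
    def test_rest_gives_flat_zero_bold(self):
        phi = HemodynamicParams()
        y = hemodynamic_observe(np.zeros((1, 300)), phi, dt=0.1)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_boxcar_transient_against_independent_integrator(self):
        """Euler-in-log-space agrees with an adaptive solver of the same ODEs."""
        phi = HemodynamicParams()
        dt = 0.02
        T = int(30 / dt)
        x = np.zeros(T)
        x[: int(1.0 / dt)] = 1.0  # 1-s boxcar of neural activity

        def reference_rhs(t, state):
            sh, f, v, q = state
            fv = v ** (1 / phi.alpha)
            ef = 1 - (1 - phi.e0) ** (1 / f)
            xi = 1.0 if t < 1.0 else 0.0
            return [
                xi - phi.kappa * sh - phi.gamma * (f - 1),
                sh,
                (f - fv) / phi.tau,
                (f * ef / phi.e0 - fv * q / v) / phi.tau,
            ]

        sol = solve_ivp(
            reference_rhs, (0, 30), [0, 1, 1, 1], t_eval=np.arange(T) * dt,
            rtol=1e-8, atol=1e-10,
        )
        k1, k2, k3 = 7 * phi.e0, 2.0, 2 * phi.e0 - 0.2
        v_ref, q_ref = sol.y[2], sol.y[3]
        y_ref = phi.v0 * (k1 * (1 - q_ref) + k2 * (1 - q_ref / v_ref) + k3 * (1 - v_ref))

        y = hemodynamic_observe(x[None, :], phi, dt=dt)[0]
        assert np.max(np.abs(y - y_ref)) < 0.02 * np.max(np.abs(y_ref))
        peak_t = np.argmax(y) * dt
        assert 3.0 <= peak_t <= 8.0
        assert abs(y[-1]) < 0.2 * y.max()  # returns toward baseline

    def test_small_signal_linearity(self):
        phi = HemodynamicParams()
        dt = 0.1
        x = np.zeros(400)
        x[10:20] = 0.01
        y1 = hemodynamic_observe(x[None, :], phi, dt=dt)[0]
        y2 = hemodynamic_observe(2 * x[None, :], phi, dt=dt)[0]
        assert y2.max() == pytest.approx(2 * y1.max(), rel=0.15)

    def test_derivative_at_equilibrium_is_zero(self):
        phi = HemodynamicParams()
        np.testing.assert_allclose(
            hemodynamic_derivative(np.zeros(4), 0.0, phi), 0.0, atol=1e-15
        )


class TestIntegrate:
    def test_zero_inputs_zero_trajectories(self, two_region):
        structure, params = two_region
        streams = impulse_streams(0.1375, 800, [50])
        streams.u[:] = 0.0
        traj = integrate(structure, params, streams, np.arange(0, 800, 8))
        np.testing.assert_array_equal(traj.x, 0.0)
        np.testing.assert_array_equal(traj.r, 0.0)
        np.testing.assert_allclose(traj.y_pred, 0.0, atol=1e-12)
        expected_rt = 3 / (1 + np.exp(-100 * params.rho))
        np.testing.assert_allclose(traj.s_pred, expected_rt, rtol=1e-12)

    def test_matches_pure_python_composition(self, two_region):
        """The fast kernel equals step-by-step composition of the layer maps."""
        structure, params = two_region
        dt = 0.1375
        n = 240
        streams = impulse_streams(dt, n, [30, 100, 170], invalid=[0, 1, 0])
        traj = integrate(structure, params, streams, np.arange(0, n, 8))
        x = np.zeros(2)
        r = 0.0
        z = np.zeros((2, 4))
        for k in range(n):
            u_k = streams.u[:, k]
            x_new = x + dt * neural_derivative(x, u_k, params)
            r = response_evolve(r, x, u_k, params)
            for i in range(2):
                z[i] = z[i] + dt * hemodynamic_derivative(z[i], x[i], params.phi)
            x = x_new
            np.testing.assert_allclose(traj.x[k + 1], x, atol=1e-10)
            np.testing.assert_allclose(traj.r[k + 1], r, atol=1e-10)
            np.testing.assert_allclose(traj.z[k + 1], z, atol=1e-10)

    def test_behavioral_branch_never_feeds_back(self, two_region):
        structure, params = two_region
        streams = impulse_streams(0.1375, 600, [40, 200, 360], invalid=[0, 1, 0])
        sample_bins = np.arange(0, 600, 8)
        base = integrate(structure, params, streams, sample_bins)
        loud = params.copy()
        loud.ar[0] = 5.0
        loud.decay = 0.9
        loud.rho = 0.4
        alt = integrate(structure, loud, streams, sample_bins)
        np.testing.assert_array_equal(base.y_pred, alt.y_pred)
        np.testing.assert_array_equal(base.x, alt.x)

    def test_step_halving_converges_on_smooth_input(self, two_region):
        """Halving dt with the same smooth input barely moves the BOLD."""
        structure, params = two_region
        dt = 1.1 / 8
        n = 800
        t = np.arange(n) * dt
        bump = 0.5 * np.sin(2 * np.pi * t / 40.0) ** 2  # slow smooth drive
        coarse = InputStreams(
            dt_s=dt,
            u=np.vstack([bump, np.zeros(n)]),
            centered=False,
            onset_bins=np.array([100]),
        )
        fine = InputStreams(
            dt_s=dt / 2,
            u=np.repeat(coarse.u, 2, axis=1),
            centered=False,
            onset_bins=np.array([200]),
        )
        sample = np.arange(0, n, 8)
        yc = integrate(None, params, coarse, sample).y_pred
        yf = integrate(
            None, params, fine, sample * 2,
            rt_bins=rt_read_bins(fine.onset_bins, 16, fine.n_bins),
        ).y_pred
        rel = np.linalg.norm(yc - yf) / np.linalg.norm(yf)
        assert rel < 0.01

    def test_rt_predictions_strictly_within_bounds(self, two_region, small_design):
        structure, params = two_region
        streams = build_input_streams(small_design, 1.1 / 8, center=True)
        traj = integrate(structure, params, streams, np.arange(0, streams.n_bins, 8))
        assert np.all(traj.s_pred > 0.0)
        assert np.all(traj.s_pred < 3.0)

    def test_mask_violation_rejected_at_validation(self, two_region):
        structure, params = two_region
        bad = params.copy()
        bad.B[0, 0, 1] = 1.0  # u1 carries no modulation in this structure
        streams = impulse_streams(0.1375, 100, [10])
        with pytest.raises(ValueError, match="outside the structure mask"):
            integrate(structure, bad, streams, np.arange(0, 100, 8))

    def test_divergent_trajectory_reports_time_bin(self):
        structure = default_posner_structure(("A-L", "A-R"), ("A-L",))
        p = BDCMParams.zeros(structure)
        p.A[:] = [[5.0, 0.0], [0.0, 5.0]]  # explosive dynamics
        p.C[:, 0] = 1.0
        streams = impulse_streams(0.5, 400, [5])
        with pytest.warns(UserWarning, match="stability"):
            with pytest.raises(FloatingPointError, match="micro-time bin"):
                integrate(None, p, streams, np.arange(0, 400, 8))

    def test_coarse_step_warns(self, two_region):
        structure, params = two_region
        streams = impulse_streams(1.2, 40, [5])
        streams.u[:] = 0.0  # rest: only the step-size check should trip
        with pytest.warns(UserWarning, match="stability"):
            integrate(structure, params, streams, np.arange(0, 40, 8))
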