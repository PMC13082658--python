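"""Arm dynamics: kinematic map, activation law, equations of motion, RK4
integration and the forward-simulation oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agearm import (ArmGeometry, MuscleParams, TaskConfig, activation_rate,
                    forward_simulate, muscle_lengths, rk4_step,
                    state_derivative)
from agearm.dynamics import equilibrium_activations, muscle_forces

GEOM = ArmGeometry()
BASE = MuscleParams()


class TestKinematics:
    def test_resting_angle_gives_optimal_lengths(self):
        lf, le = muscle_lengths(math.pi / 2, GEOM)
        assert lf == pytest.approx(0.32, abs=1e-15)
        assert le == pytest.approx(0.32, abs=1e-15)

    @pytest.mark.parametrize("deg,expected_flex,expected_ext", [
        (135.0, 0.288584, 0.351416), (45.0, 0.351416, 0.288584)])
    def test_flexed_and_extended_postures(self, deg, expected_flex, expected_ext):
        lf, le = muscle_lengths(math.radians(deg), GEOM)
        assert lf == pytest.approx(expected_flex, abs=1e-6)
        assert le == pytest.approx(expected_ext, abs=1e-6)

    def test_lengths_sum_to_twice_l0(self):
        theta = np.linspace(0, math.pi, 101)
        lf, le = muscle_lengths(theta, GEOM)
        np.testing.assert_allclose(lf + le, 2 * GEOM.l0, rtol=1e-15)


class TestActivationRate:
    def test_equilibrium(self):
        assert activation_rate(0.5, 0.5, BASE) == 0.0

    def test_activation_sign_and_scale(self):
        rate = activation_rate(0.0, 1.0, BASE)
        assert 0.5 / BASE.alpha_a < rate < 4.0 / BASE.alpha_a

    def test_frozen_deactivation_rate(self):
        # Thelen-style law at a=1, u=0: -(0.5 + 1.5)/alpha_d
        assert activation_rate(1.0, 0.0, BASE) == pytest.approx(
            -30.769230769230766, rel=1e-12)

    def test_simple_model_constant_time_constants(self):
        p = replace(BASE, activation_model="simple")
        assert activation_rate(0.0, 1.0, p) == pytest.approx(1 / p.alpha_a)
        assert activation_rate(1.0, 0.0, p) == pytest.approx(-1 / p.alpha_d)


class TestStateDerivative:
    def test_symmetric_state_has_no_angular_acceleration(self):
        x = [math.pi / 2, 0.0, 0.3, 0.3]
        dx = state_derivative(x, 0.3, 0.3, BASE, GEOM)
        assert dx[1] == pytest.approx(0.0, abs=1e-12)

    def test_torque_to_acceleration_arithmetic(self):
        # domega/dt = r (F_flex - F_ext) / I; a 100 N imbalance -> 58.14 rad/s^2
        x = [math.pi / 2 + 0.1, 0.05, 0.4, 0.2]
        Ff, Fe = muscle_forces(x, BASE, GEOM)
        dx = state_derivative(x, 0.0, 0.0, BASE, GEOM)
        assert dx[1] == pytest.approx(GEOM.r * (Ff - Fe) / GEOM.I, rel=1e-12)
        assert 0.04 * 100.0 / 0.0688 == pytest.approx(58.14, abs=0.005)

    def test_passive_force_extends_from_flexed_rest(self):
        p = replace(BASE, c1=0.09)
        dx = state_derivative([3 * math.pi / 4, 0.0, 0.0, 0.0], 0.0, 0.0, p, GEOM)
        assert dx[1] < 0  # stretched extensor's passive tension wins


class TestRK4:
    def test_fixed_point(self):
        x = np.array([math.pi / 2, 0.0, 0.3, 0.3])
        x1 = rk4_step(x, 0.3, 0.3, 0.005, BASE, GEOM)
        np.testing.assert_allclose(x1, x, atol=1e-14)

    def test_convergence_order(self):
        x0 = np.array([3 * math.pi / 4, 0.0, 0.2, 0.1])
        u = (0.3, 0.8)

        def integrate(dt, T=0.04):
            x = x0.copy()
            for _ in range(int(round(T / dt))):
                x = rk4_step(x, *u, dt, BASE, GEOM)
            return x

        ref = integrate(5e-5)
        dts = np.array([0.004, 0.002, 0.001, 0.0005])
        errs = np.array([np.linalg.norm(integrate(dt) - ref) for dt in dts])
        # least-squares order fit; the sharp (s=500) sigmoid regions make the
        # step-to-step ratios ragged, but the overall rate is 4th order
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert 3.3 < slope < 5.5

    def test_kinematic_identity_preserved(self):
        x = np.array([2.0, 1.0, 0.5, 0.2])
        for _ in range(10):
            x = rk4_step(x, 0.7, 0.1, 0.005, BASE, GEOM)
        lf, le = muscle_lengths(x[0], GEOM)
        assert lf + le == pytest.approx(2 * GEOM.l0, rel=1e-15)


class TestForwardSimulate:
    def test_no_forces_no_motion(self):
        p = replace(BASE, c1=0.0)
        traj = forward_simulate([math.pi / 2 + 0.3, 0.0, 0.0, 0.0],
                                np.zeros((80, 2)), p, GEOM)
        assert np.max(np.abs(traj.states - traj.states[0])) < 1e-14

    def test_flexor_step_flexes(self):
        u = np.zeros((40, 2))
        u[:, 0] = 1.0
        traj = forward_simulate([math.pi / 2, 0.0, 0.0, 0.0], u, BASE, GEOM)
        assert np.all(np.diff(traj.states[5:20, 0]) > 0)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_activations_stay_in_box(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.uniform(0, 1, size=(80, 2))
        p = replace(BASE, alpha_a=0.15 * BASE.alpha_a, alpha_d=0.15 * BASE.alpha_d)
        traj = forward_simulate([3 * math.pi / 4, 0.0, 0.2, 0.7], u, p, GEOM)
        a = traj.states[:, 2:]
        assert np.all(a >= -1e-12) and np.all(a <= 1 + 1e-12)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(7)
        u = rng.uniform(0, 1, size=(60, 2))
        x0 = np.array([3 * math.pi / 4, 0.0, 0.1, 0.3])
        traj = forward_simulate(x0, u, BASE, GEOM)
        x0m = np.array([math.pi - x0[0], -x0[1], x0[3], x0[2]])
        traj_m = forward_simulate(x0m, u[:, ::-1], BASE, GEOM)
        np.testing.assert_allclose(traj_m.states[:, 0],
                                   math.pi - traj.states[:, 0], atol=1e-12)
        np.testing.assert_allclose(traj_m.states[:, 1], -traj.states[:, 1],
                                   atol=1e-12)
        np.testing.assert_allclose(traj_m.states[:, 2:], traj.states[:, [3, 2]],
                                   atol=1e-12)

    def test_angular_momentum_matches_torque_integral(self):
        # fine-step simulation so the trapezoid quadrature error is negligible
        dt = 5e-5
        N = 2000
        u = np.zeros((N, 2))
        u[:, 1] = 0.8
        x0 = [3 * math.pi / 4, 0.0, 0.0, 0.0]
        traj = forward_simulate(x0, u, BASE, GEOM, dt=dt)
        torque = np.array([GEOM.r * np.subtract(*muscle_forces(x, BASE, GEOM))
                           for x in traj.states])
        impulse = np.trapezoid(torque, dx=dt)
        dL = GEOM.I * (traj.states[-1, 1] - traj.states[0, 1])
        assert impulse == pytest.approx(dL, rel=1e-6)


class TestEquilibrium:
    def test_no_stiffness_rest_is_free(self):
        p = replace(BASE, c1=0.0)
        assert equilibrium_activations(3 * math.pi / 4, p, GEOM) == (0.0, 0.0)

    def test_symmetric_posture_is_free(self):
        assert equilibrium_activations(math.pi / 2, BASE, GEOM) == (0.0, 0.0)

    def test_frozen_flexed_balance(self):
        p = replace(BASE, c1=0.09)
        af, ae = equilibrium_activations(3 * math.pi / 4, p, GEOM)
        assert ae == 0.0
        assert af == pytest.approx(0.06139254860316137, rel=1e-9)
        # and it indeed zeroes the net torque
        dx = state_derivative([3 * math.pi / 4, 0.0, af, ae], 0.0, 0.0, p, GEOM)
        assert abs(dx[1]) < 1e-9
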