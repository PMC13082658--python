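"""Objective terms, initial guess and optimal-control solution structure."""

import math
from dataclasses import replace

import numpy as np
import pytest

from agearm import (ArmGeometry, MuscleParams, TaskConfig, forward_simulate,
                    initial_guess, muscle_lengths, objective_augmented,
                    objective_end, objective_sse, smooth_abs, solve_ocp)
from agearm.metrics import excitation_bursts
from conftest import GEOM, TASK, solve_cached

# per-node squared length error with both muscles displaced by the full
# 90-degree excursion: 2 * (r * pi/2)^2
FULL_ERR = 2 * (0.04 * math.pi / 2) ** 2


def _states_at(theta, n=81):
    states = np.zeros((n, 4))
    states[:, 0] = theta
    return states


class TestObjectives:
    def test_zero_at_target(self):
        assert objective_sse(_states_at(TASK.theta_target), TASK) == 0.0
        assert objective_end(_states_at(TASK.theta_target), TASK) == 0.0

    def test_all_nodes_at_start(self):
        J = objective_sse(_states_at(TASK.theta_start), TASK)
        assert J == pytest.approx(80 * FULL_ERR, rel=1e-9)
        assert J == pytest.approx(0.6317, abs=2e-4)

    def test_end_term_at_start(self):
        Jend = objective_end(_states_at(TASK.theta_start), TASK)
        assert Jend == pytest.approx(0.01 * FULL_ERR, rel=1e-9)
        assert Jend == pytest.approx(7.896e-5, abs=1e-7)

    def test_end_term_linear_in_w(self):
        t2 = replace(TASK, w=0.02)
        s = _states_at(TASK.theta_start)
        assert objective_end(s, t2) == pytest.approx(2 * objective_end(s, TASK))

    def test_single_muscle_displacement(self):
        # displace the joint so each muscle is off-target by delta
        delta = 0.01  # m
        dtheta = delta / GEOM.r
        states = _states_at(TASK.theta_target + dtheta, n=11)
        J = objective_sse(states, TASK)
        assert J == pytest.approx(10 * 2 * delta ** 2, rel=1e-9)

    def test_initial_node_excluded_by_default(self):
        states = _states_at(TASK.theta_start)
        states[1:, 0] = TASK.theta_target
        assert objective_sse(states, TASK) == 0.0
        inc = replace(TASK, include_initial_node=True)
        assert objective_sse(states, inc) == pytest.approx(FULL_ERR, rel=1e-9)


class TestSmoothAbs:
    def test_saturated_value(self):
        assert smooth_abs(0.5, 100.0) == pytest.approx(0.5, rel=1e-12)

    def test_even(self):
        x = np.linspace(-2, 2, 41)
        np.testing.assert_allclose(smooth_abs(x), smooth_abs(-x), rtol=1e-12)

    def test_augmented_reduces_to_plain_at_rest(self):
        p = replace(MuscleParams(), c1=0.0)
        task = replace(TASK, objective_variant="augmented")
        states = _states_at(TASK.theta_start)
        controls = np.zeros((80, 2))
        J_plain = objective_sse(states, task) + objective_end(states, task)
        assert objective_augmented(states, controls, task, p) == pytest.approx(
            J_plain, rel=1e-12)

    def test_augmented_adds_excitation_cost(self):
        p = replace(MuscleParams(), c1=0.0)
        task = replace(TASK, objective_variant="augmented")
        states = _states_at(TASK.theta_start)
        controls = np.full((80, 2), 0.5)
        J0 = objective_augmented(states, np.zeros((80, 2)), task, p)
        J1 = objective_augmented(states, controls, task, p)
        assert J1 - J0 == pytest.approx(task.W_exc * 160 * 0.25, rel=1e-9)


class TestInitialGuess:
    def test_endpoint_and_midpoint_lengths(self):
        states, controls = initial_guess(TASK)
        lf, le = muscle_lengths(states[:, 0], GEOM)
        lf_s, le_s = muscle_lengths(TASK.theta_start, GEOM)
        lf_t, le_t = muscle_lengths(TASK.theta_target, GEOM)
        assert lf[0] == pytest.approx(lf_s) and le[0] == pytest.approx(le_s)
        assert lf[-1] == pytest.approx(lf_t) and le[-1] == pytest.approx(le_t)
        assert lf[40] == pytest.approx(0.5 * (lf_s + lf_t), rel=1e-12)
        assert np.all(controls == 0.0)


class TestSolution:
    def test_replay_consistency(self, baseline_solution):
        """Replaying the optimal controls through the forward simulator must
        reproduce the solver's state trajectory (shooting consistency)."""
        sol = baseline_solution
        traj = forward_simulate(sol.x0, sol.controls, sol.params, sol.geometry)
        assert np.max(np.abs(traj.states - sol.states)) <= 1e-6
        assert sol.feasibility <= 1e-6

    def test_controls_within_bounds(self, baseline_solution):
        u = baseline_solution.controls.u
        assert np.all(u >= 0.0) and np.all(u <= 1.0)

    def test_terminal_rest(self, baseline_solution):
        assert abs(baseline_solution.states[-1, 1]) < 1e-6

    def test_warm_restart_is_stationary(self, baseline_solution):
        """Re-solving from the optimum only polishes within the solver's
        convergence scatter (~1e-6 relative in J)."""
        sol2 = solve_ocp(baseline_solution.params, GEOM, TASK,
                         guess=baseline_solution)
        assert abs(sol2.J - baseline_solution.J) <= 1e-6 * (1 + baseline_solution.J)

    def test_mirror_task_symmetry(self, baseline_solution):
        """Flexion 45->135 with muscle roles swapped is the same problem; the
        objectives agree to well within convergence scatter."""
        sol_m = solve_cached(MuscleParams(), task=TASK.mirrored())
        assert sol_m.J == pytest.approx(baseline_solution.J, rel=1e-4)

    def test_solver_cross_check(self, baseline_solution):
        """The augmented-Lagrangian solution matches an independent SLSQP
        solve of the equality-constrained program."""
        sol_s = solve_ocp(MuscleParams(), GEOM, TASK, method="slsqp",
                          maxiter=800, guess=baseline_solution)
        assert sol_s.J == pytest.approx(baseline_solution.J, rel=1e-4)
        assert abs(sol_s.states[-1, 1]) < 1e-6

    def test_triphasic_pattern(self, baseline_solution):
        """Agonist burst, antagonist braking burst, second agonist burst, and
        sustained co-excitation after the movement."""
        u = baseline_solution.controls.u
        ag, ant = u[:, 1], u[:, 0]  # extension task: agonist = extensor
        ag_bursts = excitation_bursts(ag)
        ant_bursts = excitation_bursts(ant)
        assert len(ag_bursts) >= 2
        assert len(ant_bursts) >= 1
        # ordering: first agonist burst starts before the antagonist burst,
        # which starts before the second agonist burst
        assert ag_bursts[0][0] < ant_bursts[0][0] < ag_bursts[1][0]
        # sustained terminal co-activation of both muscles
        a = baseline_solution.states[-10:, 2:]
        assert np.all(a.mean(axis=0) > 0.01)

    def test_agonist_speed_respects_vmax(self, baseline_solution):
        """Peak contraction speed approaches but does not meaningfully exceed
        vmax (eccentric/smoothing tolerance)."""
        sol = baseline_solution
        p, g = sol.params, sol.geometry
        v_norm = np.abs(g.r * sol.states[:, 1] / (g.l0 * p.vmax))
        assert v_norm.max() <= 1.05
        assert v_norm.max() > 0.5  # and the movement is genuinely fast

    def test_initial_state_equilibrium(self, baseline_solution):
        x0 = baseline_solution.x0
        assert x0[0] == TASK.theta_start
        assert x0[1] == 0.0
        # extension task from a flexed posture: flexor balances the stretched
        # extensor's passive force
        assert x0[2] > 0 and x0[3] == 0.0

    def test_bad_guess_shape_rejected(self):
        with pytest.raises(ValueError):
            solve_ocp(MuscleParams(), GEOM, TASK, guess=np.zeros((10, 2)))
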