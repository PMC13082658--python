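"""Point-to-point optimal control: transcription and solution.

The movement is transcribed by single shooting: the decision variables are
the piecewise-constant excitations of both muscles over the N = T/dt steps,
states are propagated through the RK4 integrator, and the nonlinear program

    minimise    J(u) = sum of squared muscle-length errors at nodes 1..N
                       + w * terminal squared error
    subject to  omega(T) = 0,   0 <= u <= 1

is solved with exact discrete-adjoint gradients (complex-step Jacobians of
the RK4 step map).  The default solver is an augmented-Lagrangian scheme:
bound-constrained L-BFGS-B inner solves of
L = J + lambda h + (rho/2) h^2 with multiplier updates on the terminal-rest
residual h = omega(T), which converges in a few hundred gradient
evaluations; SLSQP on the equality-constrained program is available as a
cross-check (``method='slsqp'``).  Because the states are always the exact
integrator rollout of the controls, the shooting defects of an equivalent
multiple-shooting transcription are satisfied by construction, and replaying
the returned controls through :func:`agearm.dynamics.forward_simulate`
reproduces the returned states to machine precision.

The initial node is fixed: the joint starts at rest at ``theta_start`` with
the minimal static-equilibrium activations (the muscle stretched beyond
slack carries passive tension, so its opponent must be active to hold the
joint still; with zero passive stiffness both initial activations are zero).
The terminal position is penalised, not constrained; terminal rest is the
hard constraint omega(T) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _kernel
from .dynamics import equilibrium_activations, muscle_lengths, forward_simulate
from .params import ArmGeometry, MuscleParams, TaskConfig, pack_params

__all__ = [
    "ExcitationSchedule",
    "OptimalSolution",
    "objective_sse",
    "objective_end",
    "objective_augmented",
    "smooth_abs",
    "initial_guess",
    "solve_ocp",
]


@dataclass
class ExcitationSchedule:
    """Piecewise-constant bilateral excitations: u[i] = (u_flex, u_ext)."""

    u: np.ndarray
    dt: float = 0.005

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 2 or self.u.shape[1] != 2:
            raise ValueError("schedule must have shape (N, 2)")

    @property
    def N(self) -> int:
        return self.u.shape[0]

    @property
    def u_flex(self) -> np.ndarray:
        return self.u[:, 0]

    @property
    def u_ext(self) -> np.ndarray:
        return self.u[:, 1]


def _length_errors(states, task: TaskConfig, g: ArmGeometry):
    lf, le = muscle_lengths(states[:, 0], g)
    lft, let = muscle_lengths(task.theta_target, g)
    return (lf - lft) ** 2 + (le - let) ** 2


def objective_sse(states, task: TaskConfig, g: ArmGeometry = ArmGeometry()):
    """Running squared muscle-length error (m^2), summed over nodes 1..N
    (node 0 is fixed and only shifts the objective when included)."""
    errs = _length_errors(np.asarray(states, dtype=float), task, g)
    start = 0 if task.include_initial_node else 1
    return float(np.sum(errs[start:]))


def objective_end(states, task: TaskConfig, g: ArmGeometry = ArmGeometry()):
    """Terminal-position penalty w * squared length error at the final node."""
    errs = _length_errors(np.asarray(states, dtype=float), task, g)
    return float(task.w * errs[-1])


def smooth_abs(x, s=100.0):
    """Smooth absolute value x * tanh(x * s); even, ~|x| away from 0."""
    return x * np.tanh(np.clip(x * s, -30, 30))


def objective_augmented(states, controls, task: TaskConfig,
                        p: MuscleParams = MuscleParams(),
                        g: ArmGeometry = ArmGeometry()):
    """Objective augmented with excitation-effort and smoothed-work penalties:
    J + W_exc * sum(u^2) + W_work * dt * sum(smab(ldot * F))."""
    J = objective_sse(states, task, g) + objective_end(states, task, g)
    u = np.asarray(getattr(controls, "u", controls), dtype=float)
    J_exc = task.W_exc * float(np.sum(u ** 2))
    P = pack_params(p, g)
    work = 0.0
    for x in np.asarray(states, dtype=float)[1:]:
        Ff, Fe, ldf, lde = _kernel._forces(x.astype(np.complex128), P)
        work += smooth_abs(ldf.real * Ff.real, task.s_w)
        work += smooth_abs(lde.real * Fe.real, task.s_w)
    return J + J_exc + task.W_work * task.dt * work


@dataclass
class OptimalSolution:
    """Solver output: node states, optimal schedule and diagnostics."""

    states: np.ndarray
    controls: ExcitationSchedule
    J: float
    J_SSE: float
    J_end: float
    converged: bool
    n_iter: int
    status: int
    message: str
    feasibility: float      # max node-wise replay defect (single shooting: ~0)
    task: TaskConfig
    params: MuscleParams
    geometry: ArmGeometry
    x0: np.ndarray = field(default=None)
    #: terminal-rest constraint multiplier at the solution (augmented
    #: Lagrangian); reused when warm-starting from this solution
    lam_terminal: float = 0.0

    @property
    def theta(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.states)) * self.task.dt

    def trajectory(self):
        from .dynamics import Trajectory
        return Trajectory(t=self.t, states=self.states, controls=self.controls.u,
                          params=self.params, geometry=self.geometry)


def initial_guess(task: TaskConfig, g: ArmGeometry = ArmGeometry()):
    """Cold-start guess: muscle lengths interpolated linearly from start to
    target over the horizon; all other states and all controls zero.

    Returns (states, controls) arrays.  Under single shooting only the
    controls enter the solver; the state ramp documents the length-space
    interpolation the guess represents.
    """
    N = task.N
    theta = np.linspace(task.theta_start, task.theta_target, N + 1)
    states = np.zeros((N + 1, 4))
    states[:, 0] = theta  # linear in theta == linear in both muscle lengths
    controls = np.zeros((N, 2))
    return states, controls


def solve_ocp(p: MuscleParams, g: ArmGeometry, task: TaskConfig,
              guess=None, method: str = "auglag", maxiter: int = 2000,
              gtol: float = 1e-8, constraint_tol: float = 1e-7,
              max_outer: int = 8, ftol: float = 1e-10) -> OptimalSolution:
    """Solve the reaching OCP for one parameter set.

    ``guess`` may be None (cold start: zero excitations), an
    :class:`ExcitationSchedule`, an (N, 2) array, or an
    :class:`OptimalSolution` to warm-start from.  ``method`` selects the
    augmented-Lagrangian L-BFGS-B solver (default) or SLSQP on the
    equality-constrained program ('slsqp'; slower, used as a cross-check).
    ``maxiter``/``gtol`` govern the inner L-BFGS-B solves, ``constraint_tol``
    and ``max_outer`` the multiplier loop, ``ftol`` the SLSQP path.
    """
    N = task.N
    a_flex0, a_ext0 = equilibrium_activations(task.theta_start, p, g)
    x0 = np.array([task.theta_start, 0.0, a_flex0, a_ext0])

    lam0 = 0.0
    if guess is None:
        u0 = initial_guess(task, g)[1]
    elif isinstance(guess, OptimalSolution):
        u0 = guess.controls.u.copy()
        lam0 = guess.lam_terminal
    else:
        u0 = np.asarray(getattr(guess, "u", guess), dtype=float).copy()
    if u0.shape != (N, 2):
        raise ValueError(f"guess has shape {u0.shape}, expected {(N, 2)}")

    P = pack_params(p, g)
    variant = 1.0 if task.objective_variant == "augmented" else 0.0
    include0 = 1.0 if task.include_initial_node else 0.0
    args = (x0, P, task.dt, task.theta_target, task.w, variant,
            task.W_exc, task.W_work, task.s_w, include0)
    bounds = [(0.0, 1.0)] * (2 * N)

    lam_final = lam0
    if method == "slsqp":
        cache = {}

        def evaluate(z):
            key = z.tobytes()
            if key not in cache:
                cache.clear()
                cache[key] = _kernel.objective_and_gradient(z.reshape(N, 2), *args)
            return cache[key]

        res = minimize(
            lambda z: evaluate(z)[0], u0.ravel(),
            jac=lambda z: evaluate(z)[1].ravel(),
            bounds=bounds,
            constraints=[{"type": "eq",
                          "fun": lambda z: np.array([evaluate(z)[2]]),
                          "jac": lambda z: evaluate(z)[3].reshape(1, -1)}],
            method="SLSQP",
            options={"maxiter": maxiter, "ftol": ftol},
        )
        z_opt, n_iter = res.x, int(res.nit)
        ok, msg = res.status == 0, str(res.message)
    elif method == "auglag":
        lam = lam0
        rho = 10.0
        z_opt = u0.ravel()
        n_iter = 0
        ok, msg = False, ""
        for _ in range(max_outer):
            cache = {}

            def evaluate(z, lam=lam, rho=rho):
                key = z.tobytes()
                if key not in cache:
                    cache.clear()
                    J, gJ, h, gh, _ = _kernel.objective_and_gradient(
                        z.reshape(N, 2), *args)
                    L = J + lam * h + 0.5 * rho * h * h
                    gL = gJ.ravel() + (lam + rho * h) * gh.ravel()
                    cache[key] = (L, gL, h)
                return cache[key]

            res = minimize(lambda z: evaluate(z)[0], z_opt,
                           jac=lambda z: evaluate(z)[1],
                           bounds=bounds, method="L-BFGS-B",
                           options={"maxiter": maxiter, "maxcor": 30,
                                    "ftol": 1e-14, "gtol": gtol})
            z_opt = res.x
            n_iter += int(res.nit)
            hval = evaluate(z_opt)[2]
            ok, msg = res.status == 0, str(res.message)
            lam_final = lam + rho * hval
            if abs(hval) < constraint_tol:
                break
            lam = lam_final
            rho = min(rho * 10.0, 1e8)
    else:
        raise ValueError(f"unknown method {method!r}")

    u_opt = np.clip(z_opt.reshape(N, 2), 0.0, 1.0)
    J, _, hval, _, states = _kernel.objective_and_gradient(u_opt, *args)
    sched = ExcitationSchedule(u_opt, dt=task.dt)

    replay = forward_simulate(x0, sched, p, g, dt=task.dt)
    feas = float(np.max(np.abs(replay.states - states)))

    J_SSE = objective_sse(states, task, g)
    J_end = objective_end(states, task, g)
    return OptimalSolution(
        states=states, controls=sched, J=float(J), J_SSE=J_SSE, J_end=J_end,
        converged=(ok and abs(hval) < 1e-6),
        n_iter=n_iter, status=int(res.status), message=msg,
        feasibility=feas, task=task, params=p, geometry=g, x0=x0,
        lam_terminal=lam_final,
    )
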