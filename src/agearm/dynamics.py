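"""Joint kinematics, equations of motion and forward simulation.

State vector: ``[theta, omega, a_flex, a_ext]`` -- elbow flexion angle (rad,
larger = more flexed), angular velocity (rad/s) and the two muscle
activations.  The joint is frictionless and moves in a horizontal plane, so
the only torques are muscular: ``I * domega/dt = r * (F_flex - F_ext)``.
Excitation-activation coupling is a first-order law with separate activation
and deactivation time constants (Thelen-style activation-dependent effective
constants by default), blended smoothly at u = a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _kernel
from .params import ArmGeometry, MuscleParams, pack_params

__all__ = [
    "muscle_lengths",
    "activation_rate",
    "state_derivative",
    "rk4_step",
    "forward_simulate",
    "equilibrium_activations",
    "Trajectory",
]


def muscle_lengths(theta, g: ArmGeometry):
    """(l_flex, l_ext) in metres; constant-moment-arm map, summing to 2 l0."""
    theta = np.asarray(theta, dtype=float)
    dl = g.r * (theta - g.theta0)
    return g.l0 - dl, g.l0 + dl


def activation_rate(a, u, p: MuscleParams):
    """da/dt for activation a under excitation u (both in [0, 1])."""
    P = pack_params(p, ArmGeometry())

    def one(av, uv):
        return _kernel._act_rate(complex(av), complex(uv), P[6], P[7],
                                 P[17], P[18]).real

    if np.isscalar(a) and np.isscalar(u):
        return one(a, u)
    aa, uu = np.broadcast_arrays(np.asarray(a, float), np.asarray(u, float))
    flat = [one(av, uv) for av, uv in zip(aa.ravel(), uu.ravel())]
    return np.array(flat).reshape(aa.shape)


def state_derivative(x, u_flex, u_ext, p: MuscleParams, g: ArmGeometry):
    """Time derivative of [theta, omega, a_flex, a_ext]."""
    P = pack_params(p, g)
    xc = np.asarray(x, dtype=np.complex128)
    return _kernel.dyn(xc, complex(u_flex), complex(u_ext), P).real


def muscle_forces(x, p: MuscleParams, g: ArmGeometry):
    """(F_flex, F_ext) tensile forces (N) at a state."""
    P = pack_params(p, g)
    Ff, Fe, _, _ = _kernel._forces(np.asarray(x, dtype=np.complex128), P)
    return Ff.real, Fe.real


def rk4_step(x, u_flex, u_ext, dt, p: MuscleParams, g: ArmGeometry,
             integrator: str = "rk4"):
    """One classical RK4 step (or explicit-trapezoid when requested)."""
    P = pack_params(p, g)
    xc = np.asarray(x, dtype=np.complex128)
    step = _kernel.rk4_step if integrator == "rk4" else _kernel.trapezoid_step
    return step(xc, complex(u_flex), complex(u_ext), dt, P).real


@dataclass
class Trajectory:
    """Simulated node trajectory: times (N+1,), states (N+1, 4), controls (N, 2)."""

    t: np.ndarray
    states: np.ndarray
    controls: np.ndarray
    params: MuscleParams
    geometry: ArmGeometry

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-node table (controls are step values; the final node
        repeats the last step's control)."""
        lf, le = muscle_lengths(self.states[:, 0], self.geometry)
        P = pack_params(self.params, self.geometry)
        F = np.array([[f.real for f in _kernel._forces(
            x.astype(np.complex128), P)[:2]] for x in self.states])
        u = np.vstack([self.controls, self.controls[-1:]])
        return pd.DataFrame({
            "time_s": self.t,
            "theta_deg": np.degrees(self.states[:, 0]),
            "omega_rad_s": self.states[:, 1],
            "a_flex": self.states[:, 2],
            "a_ext": self.states[:, 3],
            "l_flex_m": lf,
            "l_ext_m": le,
            "F_flex_N": F[:, 0],
            "F_ext_N": F[:, 1],
            "u_flex": u[:, 0],
            "u_ext": u[:, 1],
        })


def forward_simulate(x0, schedule, p: MuscleParams, g: ArmGeometry,
                     dt: float = 0.005) -> Trajectory:
    """Integrate a piecewise-constant excitation schedule with RK4.

    ``schedule`` is an (N, 2) array of [u_flex, u_ext] per step, or an
    :class:`agearm.ocp.ExcitationSchedule`.
    """
    u = np.asarray(getattr(schedule, "u", schedule), dtype=float)
    dt = float(getattr(schedule, "dt", dt))
    P = pack_params(p, g)
    X = _kernel.simulate(u, np.asarray(x0, dtype=float), P, dt)
    t = np.arange(len(u) + 1) * dt
    return Trajectory(t=t, states=X, controls=u, params=p, geometry=g)


def equilibrium_activations(theta, p: MuscleParams, g: ArmGeometry):
    """Static-balance activations (a_flex, a_ext) holding the joint at rest.

    The stretched muscle's passive force is balanced by activating the
    opposing muscle; the stretched muscle itself stays inactive.  Raises
    ``ValueError`` if balance would require activation above 1.
    """
    P = pack_params(p, g)

    def net_torque(af, ae):
        x = np.array([theta, 0.0, af, ae], dtype=np.complex128)
        return _kernel.dyn(x, 0.0j, 0.0j, P)[1].real

    passive = net_torque(0.0, 0.0)
    if abs(passive) < 1e-14:
        return 0.0, 0.0
    if passive > 0:  # net flexion torque: extensor must hold
        f = lambda a: net_torque(0.0, a)
        if f(1.0) > 0:
            raise ValueError("static balance infeasible: extensor saturated")
        return 0.0, brentq(f, 0.0, 1.0, xtol=1e-14)
    f = lambda a: net_torque(a, 0.0)
    if f(1.0) < 0:
        raise ValueError("static balance infeasible: flexor saturated")
    return brentq(f, 0.0, 1.0, xtol=1e-14), 0.0
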