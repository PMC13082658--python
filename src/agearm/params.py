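"""Model constants and parameter containers.

The model is a single frictionless elbow joint driven by two identical
antagonistic Hill-type muscles with constant moment arms.  At the resting
angle (90 degrees of flexion) both muscles sit at their optimal length
``l0``; flexing shortens the flexor and stretches the extensor by the same
amount, so the two muscle lengths always sum to ``2 l0``.

Baseline numbers describe an adult human forearm.  The five parameters that
change with age -- peak isometric force, maximum strain rate, activation and
deactivation time constants, and passive parallel stiffness -- are the ones
swept by :mod:`agearm.sweep`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

BASELINE_FMAX = 1300.0  # N; the d2 scaling rule preserves d2 * Fmax at this product

#: Table of sweep multipliers applied to the baseline value of each parameter.
SWEEP_MULTIPLIERS = {
    "Fmax": (0.5, 0.8, 1.0, 1.5),
    "alpha_a": (0.15, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
    "alpha_d": (0.15, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
    "c1": (0.0, 0.6, 1.0, 1.4, 1.8),
    "vmax": (0.75, 1.0, 1.5, 2.0),
}


@dataclass(frozen=True)
class MuscleParams:
    """Hill-type muscle parameters (shared by flexor and extensor).

    Units: forces in N, lengths in m, times in s, strain rate in optimal
    lengths per second.  ``b``, ``c`` (= ``c1, c2, c3``) and ``d`` are the
    dimensionless shape triples of the active force-length, passive parallel
    and force-velocity curves.  ``s_smooth`` is the gain of the smoothing
    used to remove cusps from the piecewise curve definitions.
    """

    Fmax: float = BASELINE_FMAX
    vmax: float = 1.6
    alpha_a: float = 0.0945
    alpha_d: float = 0.065
    l0: float = 0.32
    b: tuple[float, float, float] = (2.0, -1.3, 0.53)
    c1: float = 0.05
    c2: float = 5.0
    c3: float = 1.0
    d: tuple[float, float, float] = (4.0, 1.4, 30.24)
    s_smooth: float = 500.0
    #: 'preserve_product': d2_eff * Fmax is held at its baseline product, so
    #: absolute eccentric strength is unchanged when Fmax varies.
    #: 'literal': d2_eff = 1300 N / Fmax.
    d2_rule: str = "preserve_product"
    #: 'thelen': first-order law with activation-dependent effective time
    #: constants; 'simple': constant time constants.
    activation_model: str = "thelen"

    def __post_init__(self) -> None:
        for name in ("Fmax", "vmax", "alpha_a", "alpha_d", "l0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.c1 < 0:
            raise ValueError(f"c1 must be non-negative, got {self.c1}")
        if self.d2_rule not in ("preserve_product", "literal"):
            raise ValueError(f"unknown d2_rule {self.d2_rule!r}")
        if self.activation_model not in ("thelen", "simple"):
            raise ValueError(f"unknown activation_model {self.activation_model!r}")

    @property
    def d2_eff(self) -> float:
        """Eccentric plateau after rescaling for the current ``Fmax``."""
        if self.d2_rule == "literal":
            return BASELINE_FMAX / self.Fmax
        return self.d[1] * BASELINE_FMAX / self.Fmax

    def with_multipliers(self, **mult: float) -> "MuscleParams":
        """Return a copy with baseline values scaled by the given multipliers.

        ``c1`` multipliers scale the baseline stiffness 0.05 (so 1.8 -> 0.09).
        """
        base = MuscleParams()
        updates = {}
        for name, m in mult.items():
            if name not in SWEEP_MULTIPLIERS:
                raise KeyError(f"{name} is not a swept parameter")
            updates[name] = getattr(base, name) * m
        return replace(self, **updates)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["b"] = list(self.b)
        d["d"] = list(self.d)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MuscleParams":
        d = dict(d)
        for key in ("b", "d"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class ArmGeometry:
    """Joint geometry and lumped forearm inertia."""

    r: float = 0.04          # muscle moment arm, m
    I: float = 6.88e-2       # moment of inertia about the elbow, kg m^2
    theta0: float = math.pi / 2  # angle at which both muscles are at l0, rad
    l0: float = 0.32         # muscle resting length, m

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArmGeometry":
        return cls(**d)


@dataclass(frozen=True)
class TaskConfig:
    """Point-to-point reaching task and objective configuration.

    The default task extends the elbow from 135 to 45 degrees within
    T = 0.4 s at a 5 ms control discretisation; the terminal-position weight
    is w = 0.01.  ``objective_variant='augmented'`` adds squared-excitation
    and smoothed mechanical-work penalties.
    """

    theta_start: float = 3 * math.pi / 4
    theta_target: float = math.pi / 4
    T: float = 0.4
    dt: float = 0.005
    w: float = 0.01
    objective_variant: str = "plain"  # or "augmented"
    W_exc: float = 1e-5    # m
    W_work: float = 1e-4   # m / J
    s_w: float = 100.0     # work smoothing gain
    #: include the (fixed) initial node in the position-error sum.  The
    #: initial node contributes a constant, so this only shifts the
    #: objective, never the optimum.
    include_initial_node: bool = False

    def __post_init__(self) -> None:
        if self.objective_variant not in ("plain", "augmented"):
            raise ValueError(f"unknown objective_variant {self.objective_variant!r}")
        n = self.T / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("T must be an integer multiple of dt")

    @property
    def N(self) -> int:
        return int(round(self.T / self.dt))

    @property
    def excursion(self) -> float:
        return abs(self.theta_start - self.theta_target)

    def mirrored(self) -> "TaskConfig":
        """The task reflected about the resting angle (start and target swapped
        through theta0); used for symmetry checks."""
        th0 = math.pi / 2
        return replace(self, theta_start=2 * th0 - self.theta_start,
                       theta_target=2 * th0 - self.theta_target)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**d)


#: Task used for comparison against empirical elbow kinematics (60-degree
#: excursion instead of the sweep's 90).
EMG_TASK = TaskConfig(theta_start=math.radians(120.0),
                      theta_target=math.radians(60.0))


def pack_params(p: MuscleParams, g: ArmGeometry) -> np.ndarray:
    """Flatten parameters into the array layout used by the numba kernel."""
    return np.array([
        g.r, g.I, g.l0, g.theta0,
        p.Fmax, p.vmax, p.alpha_a, p.alpha_d,
        p.c1, p.c2, p.c3,
        p.b[0], p.b[1], p.b[2],
        p.d[0], p.d2_eff, p.d[2],
        p.s_smooth,
        0.0 if p.activation_model == "thelen" else 1.0,
    ])


def save_config(path, **sections) -> None:
    """Write dataclass sections (params=..., geometry=..., task=...) as YAML."""
    payload = {k: v.to_dict() for k, v in sections.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_config(path) -> dict:
    """Load a YAML config; returns reconstructed dataclasses per section."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = {}
    ctors = {"params": MuscleParams, "geometry": ArmGeometry, "task": TaskConfig}
    for key, val in payload.items():
        out[key] = ctors[key].from_dict(val) if key in ctors else val
    return out
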