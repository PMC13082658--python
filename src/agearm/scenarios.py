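"""Deterministic scenario and fixture factory.

Everything a test or demonstration needs can be generated here from a seed:
named parameter corners of the sweep, archetypal excitation schedules for
forward-simulation checks, static-equilibrium activation pairs, and
synthetic sweep tables with a planted linear structure for validating the
importance regression.  Identical (seed, arguments) always produce identical
payloads; the optimal-control and sweep stages themselves are seed-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import equilibrium_activations
from .ocp import ExcitationSchedule
from .params import ArmGeometry, MuscleParams, TaskConfig
from .regression import ALL_TERMS, PARAMS, _design
from .sweep import build_full_factorial

__all__ = [
    "make_corner_params",
    "make_excitation",
    "make_equilibrium_case",
    "make_regression_table",
]

#: Multipliers for the extreme corners of the sweep: 'youngest' is the
#: strongest/fastest extreme, 'oldest' the weakest/slowest/stiffest.
CORNERS = {
    "youngest": {"Fmax": 1.5, "vmax": 2.0, "alpha_a": 0.15, "alpha_d": 0.15,
                 "c1": 0.0},
    "oldest": {"Fmax": 0.5, "vmax": 0.75, "alpha_a": 2.0, "alpha_d": 2.0,
               "c1": 1.8},
    "baseline": {"Fmax": 1.0, "vmax": 1.0, "alpha_a": 1.0, "alpha_d": 1.0,
                 "c1": 1.0},
}


def make_corner_params(which: str) -> MuscleParams:
    """Parameter set at a named corner of the sweep ('youngest', 'oldest',
    'baseline')."""
    if which not in CORNERS:
        raise ValueError(f"unknown corner {which!r}; options {sorted(CORNERS)}")
    return MuscleParams().with_multipliers(**CORNERS[which])


def make_excitation(kind: str, task: TaskConfig = TaskConfig(),
                    seed: int = 0) -> ExcitationSchedule:
    """Archetypal excitation schedules on the task's control grid.

    'zero': all off.  'step': agonist (extensor for an extension task) fully
    on.  'bang_bang': agonist burst then antagonist burst with a seeded
    switch time.  'triphasic': agonist-antagonist-agonist bursts plus a
    sustained co-excitation tail, with seeded switch times.
    """
    N = task.N
    rng = np.random.default_rng(seed)
    u = np.zeros((N, 2))
    extending = task.theta_target < task.theta_start
    ag, ant = (1, 0) if extending else (0, 1)
    if kind == "zero":
        pass
    elif kind == "step":
        u[:, ag] = 1.0
    elif kind == "bang_bang":
        sw = int(rng.integers(N // 4, 3 * N // 4))
        u[:sw, ag] = 1.0
        u[sw:, ant] = 1.0
    elif kind == "triphasic":
        s1 = int(rng.integers(N // 4, N // 2))
        s2 = int(rng.integers(s1 + N // 8, s1 + N // 4))
        s3 = int(rng.integers(s2 + N // 16, min(s2 + N // 4, N - 2)))
        u[:s1, ag] = 1.0
        u[s1:s2, ant] = 1.0
        u[s2:s3, ag] = 0.6
        u[s3:, :] = 0.1  # sustained terminal co-excitation
    else:
        raise ValueError(f"unknown excitation kind {kind!r}")
    return ExcitationSchedule(u, dt=task.dt)


def make_equilibrium_case(c1: float, theta: float,
                          p: MuscleParams = MuscleParams(),
                          g: ArmGeometry = ArmGeometry()):
    """Static-balance activations (a_flex, a_ext) for a posture and stiffness."""
    from dataclasses import replace
    return equilibrium_activations(theta, replace(p, c1=c1), g)


def make_regression_table(coeffs: dict, grid: list[dict] | None = None,
                          noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Synthetic sweep table whose response is an exact linear model (plus
    optional Gaussian noise) over the normalised 16-term basis.

    ``coeffs`` maps term names (see :data:`agearm.regression.ALL_TERMS`) to
    coefficients on the normalised scale; missing terms are zero.  The table
    carries the absolute parameter columns and a 'J_RMSE' response, so it
    feeds straight into :func:`agearm.regression.fit_importance`.
    """
    unknown = set(coeffs) - set(ALL_TERMS)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    if grid is None:
        grid = build_full_factorial()
    base = MuscleParams()
    rows = []
    for mult in grid:
        p = base.with_multipliers(**mult)
        rows.append({name: getattr(p, name) for name in PARAMS})
    table = pd.DataFrame(rows)
    X = _design(table, ALL_TERMS)
    beta = np.array([coeffs.get(term, 0.0) for term in ALL_TERMS])
    y = X.to_numpy() @ beta
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(y))
    table["J_RMSE"] = y
    return table
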