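"""Shared fixtures: cached OCP solves reused across the suite.

Solves are deterministic, so caching by (params, task) is sound; the cache
is shared session-wide to keep the suite fast.  Families (e.g. the seven
deactivation-time values at zero stiffness) warm-start from the baseline
solution, the policy also used for the finer-grid sweep.
"""

from dataclasses import replace

import numpy as np
import pytest

from agearm import (ArmGeometry, MuscleParams, TaskConfig, evaluate_solution,
                    make_corner_params, solve_ocp)
from agearm.params import SWEEP_MULTIPLIERS

GEOM = ArmGeometry()
TASK = TaskConfig()

_solutions: dict = {}


def solve_cached(p: MuscleParams, task: TaskConfig = TASK, warm_from=None,
                 **kw):
    key = (p, task)
    if key not in _solutions:
        guess = _solutions.get((warm_from, task)) if warm_from else None
        _solutions[key] = solve_ocp(p, GEOM, task, guess=guess, **kw)
    return _solutions[key]


@pytest.fixture(scope="session")
def baseline_solution():
    return solve_cached(MuscleParams())


@pytest.fixture(scope="session")
def youngest_solution():
    return solve_cached(make_corner_params("youngest"))


@pytest.fixture(scope="session")
def oldest_solution():
    return solve_cached(make_corner_params("oldest"))


def _family(param: str, c1: float = None):
    """Solutions along one parameter's tested range, others at baseline."""
    base = MuscleParams()
    _ = solve_cached(base)  # ensure the warm-start source exists
    out = {}
    for m in SWEEP_MULTIPLIERS[param]:
        p = base.with_multipliers(**{param: m})
        if c1 is not None:
            p = replace(p, c1=c1)
        out[m] = solve_cached(p, warm_from=base)
    return out


@pytest.fixture(scope="session")
def alpha_d_family_zero_stiffness():
    """Seven deactivation-time solutions at c1 = 0, others baseline."""
    return _family("alpha_d", c1=0.0)


@pytest.fixture(scope="session")
def alpha_d_family_high_stiffness():
    """Seven deactivation-time solutions at c1 = 0.09, others baseline."""
    return _family("alpha_d", c1=0.09)


@pytest.fixture(scope="session")
def fmax_family():
    return _family("Fmax")


@pytest.fixture(scope="session")
def vmax_family():
    return _family("vmax")


@pytest.fixture(scope="session")
def alpha_a_family():
    return _family("alpha_a")


def metrics_of(sol):
    return evaluate_solution(sol)
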