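"""Parameter sweeps over ageing-related muscle properties.

The full factorial crosses the tested ranges of the five parameters
(4 x 4 x 7 x 7 x 5 = 3920 combinations); the finer grid varies only the
deactivation time constant and the passive stiffness at much higher
resolution, holding everything else at baseline.  Each combination is an
independent OCP solve; results are gathered into a tidy table, one row per
combination, in a deterministic order independent of worker scheduling.

``find_neutral_deactivation`` locates the deactivation time constant at
which a small change in passive stiffness leaves performance unchanged --
the boundary separating the regime where stiffness helps (fast deactivation:
the antagonist can release the passively loaded joint) from the regime where
it hurts (slow deactivation: the stretched antagonist's eccentric force
dominates).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .metrics import evaluate_solution
from .ocp import solve_ocp
from .params import ArmGeometry, MuscleParams, SWEEP_MULTIPLIERS, TaskConfig

__all__ = [
    "build_full_factorial",
    "build_finer_grid",
    "run_sweep",
    "find_neutral_deactivation",
]

_PARAM_ORDER = ("Fmax", "alpha_a", "alpha_d", "c1", "vmax")  # lexicographic


def build_full_factorial(multipliers: dict | None = None) -> list[dict]:
    """All combinations of the tested multiplier ranges, in deterministic
    lexicographic order (by parameter name, then value)."""
    mult = dict(SWEEP_MULTIPLIERS)
    if multipliers:
        mult.update(multipliers)
    names = sorted(mult)
    combos = []
    for values in itertools.product(*(sorted(mult[n]) for n in names)):
        combos.append(dict(zip(names, values)))
    return combos


def build_finer_grid(step_alpha_d: float = 0.0006, step_c1: float = 0.005,
                     alpha_d_range=(0.00975, 0.130), c1_range=(0.0, 0.09),
                     ) -> list[dict]:
    """Product grid over (alpha_d, c1) in absolute units, others at baseline.

    Steps default to 0.6 ms and 0.005 stiffness units; endpoints inclusive,
    a final partial step is clipped to the range end.  Returned dicts carry
    multipliers relative to baseline, like the factorial builder.
    """
    if step_alpha_d <= 0 or step_c1 <= 0:
        raise ValueError("steps must be positive")
    base = MuscleParams()

    def _grid(lo, hi, step):
        vals = list(np.arange(lo, hi + 0.5 * step, step))
        if vals[-1] > hi:
            vals[-1] = hi
        return vals

    combos = []
    for ad in _grid(*alpha_d_range, step_alpha_d):
        for c1 in _grid(*c1_range, step_c1):
            combos.append({
                "Fmax": 1.0, "alpha_a": 1.0,
                "alpha_d": ad / base.alpha_d,
                "c1": c1 / base.c1, "vmax": 1.0,
            })
    return combos


def _solve_one(mult: dict, base: MuscleParams, g: ArmGeometry, task: TaskConfig,
               warm_u, retry_u, solver_opts: dict):
    p = base.with_multipliers(**mult)
    sol = solve_ocp(p, g, task, guess=warm_u, **solver_opts)
    if not sol.converged and retry_u is not None:
        # one retry, warm-started from the baseline-parameter solution
        retry = solve_ocp(p, g, task, guess=retry_u, **solver_opts)
        if retry.J <= sol.J:
            sol = retry
    rec = evaluate_solution(sol)
    row = {f"{k}_mult": mult[k] for k in _PARAM_ORDER}
    row.update({
        "Fmax": p.Fmax, "alpha_a": p.alpha_a, "alpha_d": p.alpha_d,
        "c1": p.c1, "vmax": p.vmax,
        "J_SSE": sol.J_SSE, **rec.to_dict(),
        "converged": sol.converged, "n_iter": sol.n_iter,
        "feasibility": sol.feasibility,
    })
    return row


def run_sweep(grid: list[dict], base: MuscleParams = MuscleParams(),
              g: ArmGeometry = ArmGeometry(), task: TaskConfig = TaskConfig(),
              guess_policy: str = "cold", n_jobs: int = 1,
              **solver_opts) -> pd.DataFrame:
    """Solve every combination in ``grid`` and tabulate metrics.

    ``guess_policy``: 'cold' starts every solve from zero excitations (the
    policy for the full factorial); 'baseline' warm-starts each solve from
    the baseline-parameter solution (the finer-grid policy).  Rows are sorted
    by the multiplier key so output is reproducible for any worker count.
    """
    if guess_policy not in ("cold", "baseline"):
        raise ValueError(f"unknown guess_policy {guess_policy!r}")
    base_u = solve_ocp(base, g, task, **solver_opts).controls.u
    warm = base_u if guess_policy == "baseline" else None

    rows = Parallel(n_jobs=n_jobs)(
        delayed(_solve_one)(m, base, g, task, warm, base_u, solver_opts)
        for m in grid)
    df = pd.DataFrame(rows)
    df = df.sort_values([f"{k}_mult" for k in _PARAM_ORDER],
                        kind="mergesort").reset_index(drop=True)
    return df


def bisect_sign_change(fn, lo: float, hi: float, tol: float) -> float:
    """Bisection for a root of ``fn`` given a sign change over [lo, hi].

    Raises ``ValueError`` (with the endpoint values, for diagnosis) when the
    bracket does not straddle a sign change.
    """
    f_lo, f_hi = fn(lo), fn(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"no sign change over bracket: f({lo})={f_lo:.3e}, f({hi})={f_hi:.3e}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.sign(fn(mid)) == np.sign(f_lo):
            lo, f_lo = mid, fn(mid)
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_neutral_deactivation(base: MuscleParams = MuscleParams(),
                              g: ArmGeometry = ArmGeometry(),
                              task: TaskConfig = TaskConfig(),
                              c1_pair=(0.04, 0.05),
                              bracket=(0.00975, 0.130),
                              tol: float = 0.0005,
                              **solver_opts) -> float:
    """Deactivation time constant (s) at which the stiffness change
    ``c1_pair[0] -> c1_pair[1]`` leaves J_RMSE unchanged, by bisection on
    g(alpha_d) = J_RMSE(c1_hi) - J_RMSE(c1_lo); other parameters at baseline.

    Raises ``ValueError`` if g does not change sign over the bracket.
    """
    from dataclasses import replace

    warm = solve_ocp(base, g, task, **solver_opts).controls.u
    cache: dict = {}

    def g_of(ad: float) -> float:
        if ad not in cache:
            js = []
            for c1 in c1_pair:
                p = replace(base, alpha_d=ad, c1=c1)
                sol = solve_ocp(p, g, task, guess=warm, **solver_opts)
                js.append(evaluate_solution(sol).J_RMSE)
            cache[ad] = js[1] - js[0]
        return cache[ad]

    return bisect_sign_change(g_of, bracket[0], bracket[1], tol)
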