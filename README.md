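# agearm

**How do ageing muscle properties shape rapid goal-directed movement?**

`agearm` is a computational biomechanics package built around a deliberately
simple model: a frictionless elbow joint in a horizontal plane, driven by
two identical antagonistic Hill-type muscles with constant moment arms.
Optimal point-to-point movements are computed by trajectory optimisation,
and the five muscle parameters that change with age — peak isometric force
F_max, maximum strain rate v_max, activation and deactivation time
constants α_a and α_d, and passive parallel stiffness c₁ — are swept
factorially to map how each (and their interactions) limits ballistic
reaching performance.

It is aimed at motor-control and muscle physiologists who want a tractable,
fully inspectable sandbox in which causal links between muscle-level
parameters and movement-level outcomes can be established — something that
is close to impossible in vivo, where ageing changes everything at once.

## The model in brief

State x = [θ, ω, a_flex, a_ext]; dynamics

    I ω̇ = r (F_flex − F_ext),
    F   = F_max (a · f_L(l/l₀) · f_V(v) + f_P(l/l₀)),
    ȧ   = first-order excitation–activation law with constants α_a, α_d,

with smoothed Hill curves f_L, f_V, f_P (see `docs/methods.md`). The
control problem: choose piecewise-constant excitations u(t) ∈ [0,1]² on a
5 ms grid to minimise the cumulative squared muscle-length error

    J = Σᵢ (l_ag,i − l_ag,target)² + (l_ant,i − l_ant,target)²  +  w·(terminal term)

over T = 0.4 s, starting and ending at rest (ω(T) = 0). Performance is the
normalised per-muscle RMS error J_RMSE = √(J_SSE/N)/(2l₀), in units of the
muscle resting length l₀. The solver is single shooting + SLSQP with exact
adjoint gradients (complex-step Jacobians inside a numba kernel);
everything is deterministic.

## Worked example

```python
from agearm import (MuscleParams, ArmGeometry, TaskConfig,
                    solve_ocp, evaluate_solution, make_corner_params)

g, task = ArmGeometry(), TaskConfig()          # 135° -> 45°, T = 0.4 s
sol = solve_ocp(MuscleParams(), g, task)       # baseline muscle
print(evaluate_solution(sol))
```

prints

```
MetricsRecord(J_RMSE=0.0707836950609091, a_c_mean=0.20562195114170043,
              T_T=0.22573526778811992, T_S=0.25150531064410364,
              J_RMSE_rel=0.999993073782983)
```

meaning: the baseline arm reaches the 90° target in ≈ 0.226 s and is stable
inside a 1%-of-excursion band by ≈ 0.252 s; the time-normalised error is
≈ 0.0708 l₀, essentially all of it (99.999%) accrued during the ballistic
phase; the optimal solution co-activates both muscles at an average level
of ≈ 0.21. The excitations show the classic triphasic pattern — agonist
burst, antagonist braking burst, second agonist burst — plus sustained
co-excitation after the movement ends.

Age-extreme corners of the sweep:

```python
for which in ("youngest", "oldest"):
    m = evaluate_solution(solve_ocp(make_corner_params(which), g, task))
    print(which, round(m.J_RMSE, 4), round(m.T_T, 3))
# youngest 0.052 0.128
# oldest   0.0928 0.387
```

The strong/fast extreme reaches the target three times faster than the
weak/slow/stiff extreme. A command-line interface mirrors the library
(`agearm solve`, `agearm sweep`, `agearm regress`, `agearm neutral-boundary`,
`agearm curves`, `agearm fixtures`).

## Layout

| module | contents |
|---|---|
| `agearm.params` | model constants, parameter containers, sweep ranges |
| `agearm.mechanics` | smoothed Hill curves and the muscle-force map |
| `agearm.dynamics` | kinematics, equations of motion, RK4 forward simulation |
| `agearm.ocp` | objectives and the single-shooting SLSQP transcription |
| `agearm.metrics` | J_RMSE, coactivation, timing metrics, burst detection |
| `agearm.sweep` | factorial/finer grids, deterministic sweep tables, neutral-boundary bisection |
| `agearm.regression` | range-normalised importance regression, coactivation regression |
| `agearm.scenarios` | corners, excitation archetypes, equilibrium cases, planted regression tables |
| `agearm.cli` | `agearm` command-line entry point |

See `docs/methods.md` for the full model description, numerical choices and
limitations.
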