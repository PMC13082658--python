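# Methods

## Model

The arm is a single frictionless hinge (the elbow) moving in a horizontal
plane, driven by two identical antagonistic Hill-type muscles with constant
moment arm r = 0.04 m acting on a lumped forearm inertia
I = 6.88×10⁻² kg·m². At the resting angle θ₀ = 90° both muscles are at
their optimal length l₀ = 0.32 m; the kinematic map is linear,

    l_flex = l₀ − r(θ − θ₀),    l_ext = l₀ + r(θ − θ₀),

so the two lengths always sum to 2l₀ and each muscle's length error is
proportional to the angular error. The state is
x = [θ, ω, a_flex, a_ext]; the equations of motion are
I·ω̇ = r(F_flex − F_ext) with tensile Hill forces

    F = F_max · (a · f_L(l/l₀) · f_V(v) + f_P(l/l₀)),

where v is the strain rate in optimal lengths per second divided by v_max
(positive = lengthening).

### Curve definitions

The exact closed forms sit behind a single seam (`agearm.mechanics` and the
matching kernel in `agearm._kernel`) so alternative Hill formulations can be
swapped without touching the rest of the package. The implemented family:

- **Active force-length** (Brown/Loeb-style):
  f_L(l) = exp(−(((l^b₂) − 1)/b₃)^b₁) with b = [2, −1.3, 0.53]. With b₁ = 2
  the curve is analytic everywhere (finite Hessian), peaking at exactly 1
  for l = l₀.
- **Passive parallel element**:
  f_P(l) = c₁·(exp(c₂·sp(l − c₃)) − 1), where sp(x) = log(1 + e^{sx})/s is a
  softplus ramp with gain s = 500 and c = [c₁, 5, 1.0]. The softplus keeps
  f_P strictly non-negative and smooth; below the slack length the leakage
  is below 10⁻³·c₁ within half a percent of strain.
- **Force-velocity**: a Hill concentric hyperbola
  f_c = (1 + v_c)/(1 − d₁·v_c), with v_c = −1 + sp(v + 1) capped smoothly
  short of the hyperbola's pole, joined to a Katz eccentric hyperbola
  f_e = (1 + d₂_eff·d₃·v_e)/(1 + d₃·v_e), v_e = ½v(1 + tanh(sv)), by the
  sigmoid σ(v) = ½(1 + tanh(sv)); d = [4, 1.4, 30.24]. The tanh ramp on the
  eccentric argument makes the isometric normalisation exact, f_V(0) = 1;
  f_V(−1) = O(10⁻⁴); the eccentric branch saturates near d₂_eff.
- **Eccentric plateau scaling**: d₂_eff = 1.4·(1300 N)/F_max, so that
  absolute eccentric strength d₂_eff·F_max is invariant when F_max is swept
  (eccentric strength is comparatively well preserved in ageing muscle). A
  config switch (`d2_rule="literal"`) instead sets d₂_eff = 1300 N/F_max.

All smoothing uses the single gain s = 500. Every curve is analytic, which
the optimiser exploits: derivatives are obtained by the complex-step method
and are exact to machine precision.

### Excitation-activation dynamics

First-order coupling with separate activation and deactivation time
constants, Thelen-style activation dependence:

    u > a:  ȧ = (u − a) / (α_a (0.5 + 1.5a))
    u ≤ a:  ȧ = (u − a) (0.5 + 1.5a) / α_d

blended across u = a by the same tanh sigmoid (gain s). Baselines:
α_a = 94.5 ms, α_d = 65 ms. A `activation_model="simple"` switch removes the
activation dependence (constant time constants) for sensitivity checks.
Activations cannot leave [0, 1] under excitations in [0, 1]; no activation
floor is needed because the law has no division by a.

## Trajectory optimisation

The task runs T = 0.4 s at Δt = 5 ms (N = 80 piecewise-constant bilateral
excitation steps), from 135° to 45° of flexion for the sweeps (120°→60° for
the kinematic-comparison scenario). The objective is the running squared
muscle-length error summed over nodes 1..N plus a terminal term with weight
w = 0.01; the initial node is fixed and therefore excluded by default (a
config switch includes it; it only shifts the objective by a constant).
Performance is reported as

    J_RMSE = sqrt(J_SSE / N) / (2 l₀),

the normalised per-muscle error of the symmetric pair. The factor-of-two
placement is ambiguous between two readings differing by sqrt(2); both are
implemented (`rmse_metric(..., reading=...)`) and the default was frozen by
calibration against the documented corner values (0.0534 l₀ / 0.0943 l₀),
which it reproduces within ~3%.

**Transcription.** The problem is transcribed by *single shooting*: the
decision vector is the 160-dimensional excitation sequence and states are
the exact RK4 rollout. Gradients are computed by the discrete adjoint of
the RK4 step map, whose 4×4/4×2 step Jacobians come from complex-step
differentiation inside a numba kernel — exact to machine precision. The
terminal-rest condition ω(T) = 0 (terminal position is penalised, not
constrained) is handled by an augmented-Lagrangian outer loop: L-BFGS-B
minimises L = J + λω(T) + (ρ/2)ω(T)² over the box-constrained controls,
then λ is updated, until |ω(T)| < 10⁻⁷ (typically 1–3 outer rounds, a few
hundred gradient evaluations in total). SLSQP on the equality-constrained
program is available (`method="slsqp"`) and agrees with the default solver
to ~10⁻⁶ relative in J; it is an order of magnitude slower because scipy's
dense QP subproblem carries all 320 bound constraints. The solver's
convergence scatter is ~3×10⁻⁷ absolute in J, which bounds the precision of
statements like warm-restart stationarity and mirror symmetry. Because
states are eliminated, the defect constraints of a multiple-shooting
transcription hold identically: replaying the optimal controls through the
forward simulator reproduces the stored states bit-for-bit (the
`feasibility` field records the replay defect, which is 0). An
explicit-trapezoid integrator is available as a config alternative for
integration-sensitivity checks.

**Initial conditions.** The joint starts at rest. Initial activations are
the minimal static-equilibrium pair: the muscle stretched beyond slack
loads the joint passively, and its opponent activates just enough to hold
ω̇ = 0 (solved by bracketed root finding); with c₁ = 0 both are zero. This
reproduces the antagonist-as-latch configuration at t = 0 and removes two
decision variables; the one-parameter family of higher co-activated
equilibria is deliberately not searched (the optimiser can reach those
states within one step if useful).

**Initial guess.** Cold starts use zero excitations (the linear
muscle-length interpolation of the guess trajectory has no free state
variables under single shooting); the finer-grid and plane runs warm-start
from the baseline-parameter solution. Spot checks at far corners show cold
and warm starts reach the same optimum to ~10⁻⁴ relative in J.

**Augmented objective** (optional): J + W_exc·Σu² + W_work·Δt·Σ smab(l̇F|s_w)
with W_exc = 10⁻⁵ m, W_work = 10⁻⁴ m/J, smab(x|s) = x·tanh(xs), s_w = 100,
for effort-penalised variants with smoother excitations. The same adjoint
machinery covers it (the work term's state gradient is complex-stepped per
node).

## Metrics

- Coactivation a_c(t) = min(a_flex, a_ext); mean by trapezoid over [0, T].
- Time to target T_T: first linearly-interpolated entry of θ into a band of
  1% of the excursion (0.9° for the 90° task) around the target; T if never.
  The 1% band is a package choice (exposed as `tol_frac`): it reproduces
  "the worst case just reaches the target" at the oldest corner.
- Time to stable T_S: earliest time after which θ never leaves the band.
- Ballistic fraction: share of the squared-error sum accrued during the
  ballistic phase (a sum-of-squares ratio, chosen for additivity). The
  phase boundary is T_S: the movement is ballistic until it has settled.
  Splitting at T_T instead (supported by the same function) charges the
  overshoot and settling oscillations to the post-ballistic side, lowering
  the fraction for young/fast parameter sets that overshoot.

A caveat on coactivation: after stabilisation the plain objective is flat
along balanced co-contraction directions (raising both excitations while
keeping the joint still does not change the positional error), so the
post-movement coactivation level of an optimal solution is set by the
solver path, not by the objective. Coactivation statistics are therefore
always reported for cold-started solves, where the level that emerges is
the one the braking dynamics require rather than an inherited pattern.

## Sweeps and regression

The full factorial crosses F_max × v_max × α_a × α_d × c₁ over multipliers
{0.5, 0.8, 1, 1.5} × {0.75, 1, 1.5, 2} × {0.15, 0.25, 0.5, 0.75, 1, 1.5, 2}²
× {0, 0.6, 1, 1.4, 1.8} = 3920 combinations (cold starts). The finer grid
varies only α_d (0.6 ms steps) and c₁ (0.005 steps) with warm starts from
baseline; its composition is explicit configuration because step-derived
counts are convention-dependent. Rows are solved independently and sorted
by a deterministic key, so worker count cannot affect the output table.
Plane computations over (α_d, c₁) additionally warm-start each cell from
its neighbour along the stiffness axis (continuation), which avoids the
occasional inferior local optimum a plain baseline warm start can hit at
fast-deactivation/mid-stiffness cells.
Non-convergent solves (rare; typically iteration-limit flags with converged
objectives) are retried once from the baseline warm start and always kept,
flagged, in the table.

Importance regression: each parameter and the response are normalised to
[0, 1] by min/range; interactions are products of normalised mains (on a
full factorial containing 0/1 levels these already span [0, 1]; a switch
re-normalises them for sensitivity analysis). OLS coefficients are the
importances; |β| > 0.1 is "important to first order". Model variants:
all 16 terms; intercept + α_a + v_max + F_max + α_d:c₁; the same without
the interaction. The coactivation regression fits J_RMSE/max(J_RMSE)
against the raw coactivation mean.

The stiffness-neutral boundary is located by bisection on
g(α_d) = J_RMSE(c₁ = 0.05) − J_RMSE(c₁ = 0.04) over α_d ∈ [9.75, 130] ms to
0.5 ms, with solves warm-started from baseline (~20 solves).

## Problem sizes used in the shipped checks

Single solves use the full study configuration (N = 80, gtol = 10⁻⁸,
|ω(T)| < 10⁻⁷; a solve takes a few seconds). The sweep-statistics check
runs a reduced factorial — extremes plus baseline per parameter, 3⁵ = 243
combinations, warm-started — rather than the full 3920-solve factorial,
which is a multi-hour batch; the reduced grid preserves all corner
combinations and every tested sign/threshold statistic. The deactivation ×
stiffness plane check uses a 5 × 5 coarse grid over the same ranges as the
finer sweep.

## What the scenario generator does and does not emulate

Generated fixtures are model-side constructs: parameter corners, archetypal
excitation schedules (zero/step/bang-bang/triphasic), static-equilibrium
cases, and planted-coefficient regression tables. They validate the
machinery (integration, optimisation invariants, regression recovery), not
biological realism: no EMG-like noise, no electromechanical delay, no
tendon dynamics, no twitch structure. Passing tests therefore demonstrate
internal correctness and reproduction of the documented model behaviour,
not agreement with new experimental data.

## Numerical choices and degenerate inputs

- Smoothing gain s = 500 throughout; complex-step size 10⁻¹⁰⁰.
- tanh saturates explicitly beyond |arg| > 20 in the kernel (numba's
  complex tanh overflows around 355; the discarded derivative is < 10⁻¹⁷).
- The concentric hyperbola argument is capped smoothly at 0.125 (pole at
  0.25), in a region where the eccentric branch carries ~all blend weight.
- Range normalisation raises on constant vectors; the importance fit raises
  on rank-deficient designs; the coactivation fit raises on zero-variance
  responses; static balance raises if it would need activation > 1.
- Bisection raises with endpoint diagnostics if the bracket has no sign
  change.
- Everything is deterministic: identical inputs give identical objective
  values on a fixed platform; seeds only enter the synthetic fixture
  factory.

## Known limitations

- The Hill closed forms are one member of the family consistent with the
  published shape triples; absolute performance numbers shift at the
  percent level under alternative smoothing constructions (hence the seam).
- Single shooting scales poorly to long horizons or unstable dynamics; for
  this 0.4 s stable reach it is accurate and fast, but a sparse
  multiple-shooting transcription would be preferable if the model grew.
- SLSQP occasionally stops at its iteration cap with a converged-in-practice
  iterate; such rows are flagged, never dropped.
- No tendon elasticity, electromechanical delay, pennation, gravity, joint
  damping, noise, feedback delays, or energetic costs in the default
  objective.
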