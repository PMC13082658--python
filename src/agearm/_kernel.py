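"""Numba kernel: smoothed Hill curves, arm dynamics, RK4 and adjoint gradients.

Everything here operates on complex128 so that exact first derivatives can be
obtained by the complex-step method (the curve definitions are analytic:
exponentials, tanh sigmoids and rational branches).  The same functions serve
the nominal (zero-imaginary) forward simulation.

Parameter array layout (see :func:`agearm.params.pack_params`)::

    0 r   1 I   2 l0  3 theta0  4 Fmax  5 vmax  6 tau_a  7 tau_d
    8 c1  9 c2  10 c3  11 b1  12 b2  13 b3  14 d1  15 d2_eff  16 d3
    17 s_smooth  18 activation_model (0 = thelen, 1 = simple)

Two numerical guards matter.  numba's complex tanh overflows for
|Re| > ~355, so tanh saturates explicitly (the discarded derivative there is
below 1e-17).  The concentric force-velocity hyperbola has a pole at
v = 1/d1; its argument is smoothly capped well short of the pole, in a region
where the eccentric branch carries all the blend weight anyway.
"""

import numpy as np
from numba import njit

CSTEP = 1e-100  # complex-step size; derivatives are exact to machine precision


@njit(cache=True)
def _tanh(z):
    if z.real > 20.0:
        return 1.0 + 0.0j
    if z.real < -20.0:
        return -1.0 + 0.0j
    return np.tanh(z)


@njit(cache=True)
def _softplus(x, s):
    """Smooth max(x, 0) with gain s: log(1 + exp(s*x)) / s, overflow-safe."""
    t = s * x
    if t.real > 20.0:
        return x + np.exp(-t) / s
    if t.real < -20.0:
        return np.exp(t) / s
    return np.log(1.0 + np.exp(t)) / s


@njit(cache=True)
def _fl_active(l, b1, b2, b3):
    q = ((l ** b2) - 1.0) / b3
    if b1 == 2.0:
        e = q * q  # exact squaring avoids complex-pow branch-cut rounding
    else:
        e = q ** b1
    return np.exp(-e)


@njit(cache=True)
def _fl_passive(l, c1, c2, c3, s):
    return c1 * (np.exp(c2 * _softplus(l - c3, s)) - 1.0)


@njit(cache=True)
def _fv(v, d1, d2eff, d3, s):
    vc = -1.0 + _softplus(v + 1.0, s)      # concentric argument, > -1
    vc = vc - _softplus(vc - 0.125, s)      # cap short of the pole at 1/d1
    ve = 0.5 * v * (1.0 + _tanh(s * v))    # eccentric argument; exactly 0 at v=0
    fc = (1.0 + vc) / (1.0 - d1 * vc)
    fe = (1.0 + d2eff * d3 * ve) / (1.0 + d3 * ve)
    sig = 0.5 * (1.0 + _tanh(s * v))
    return (1.0 - sig) * fc + sig * fe


@njit(cache=True)
def _act_rate(a, u, tau_a, tau_d, s, model):
    if model == 0.0:  # Thelen-style activation-dependent effective constants
        r_act = (u - a) / (tau_a * (0.5 + 1.5 * a))
        r_de = (u - a) * (0.5 + 1.5 * a) / tau_d
    else:
        r_act = (u - a) / tau_a
        r_de = (u - a) / tau_d
    sig = 0.5 * (1.0 + _tanh(s * (u - a)))
    return sig * r_act + (1.0 - sig) * r_de


@njit(cache=True, inline="always")
def _forces_s(th, om, af, ae, P):
    """Scalar tensile flexor/extensor forces (N) at a state."""
    r = P[0]; l0 = P[2]; th0 = P[3]
    Fmax = P[4]; vmax = P[5]
    c1 = P[8]; c2 = P[9]; c3 = P[10]
    b1 = P[11]; b2 = P[12]; b3 = P[13]
    d1 = P[14]; d2eff = P[15]; d3 = P[16]; s = P[17]
    dl = (r / l0) * (th - th0)
    lf = 1.0 - dl
    le = 1.0 + dl
    vf = -(r / l0) * om / vmax  # normalized strain rate, lengthening positive
    ve = (r / l0) * om / vmax
    Ff = Fmax * (af * _fl_active(lf, b1, b2, b3) * _fv(vf, d1, d2eff, d3, s)
                 + _fl_passive(lf, c1, c2, c3, s))
    Fe = Fmax * (ae * _fl_active(le, b1, b2, b3) * _fv(ve, d1, d2eff, d3, s)
                 + _fl_passive(le, c1, c2, c3, s))
    return Ff, Fe


@njit(cache=True)
def _forces(x, P):
    """Tensile flexor/extensor forces and lengthening rates at a state.

    Returns (F_flex, F_ext, ldot_flex, ldot_ext); forces in N, rates in m/s.
    """
    Ff, Fe = _forces_s(x[0], x[1], x[2], x[3], P)
    return Ff, Fe, -P[0] * x[1], P[0] * x[1]


@njit(cache=True, inline="always")
def _dyn_s(th, om, af, ae, uf, ue, P):
    """Scalar state derivative (allocation-free hot path)."""
    Ff, Fe = _forces_s(th, om, af, ae, P)
    return (om, P[0] * (Ff - Fe) / P[1],
            _act_rate(af, uf, P[6], P[7], P[17], P[18]),
            _act_rate(ae, ue, P[6], P[7], P[17], P[18]))


@njit(cache=True, inline="always")
def _rk4_s(th, om, af, ae, uf, ue, dt, P):
    """Scalar classical RK4 step."""
    a1, b1, c1, d1 = _dyn_s(th, om, af, ae, uf, ue, P)
    h = 0.5 * dt
    a2, b2, c2, d2 = _dyn_s(th + h * a1, om + h * b1, af + h * c1,
                            ae + h * d1, uf, ue, P)
    a3, b3, c3, d3 = _dyn_s(th + h * a2, om + h * b2, af + h * c2,
                            ae + h * d2, uf, ue, P)
    a4, b4, c4, d4 = _dyn_s(th + dt * a3, om + dt * b3, af + dt * c3,
                            ae + dt * d3, uf, ue, P)
    w = dt / 6.0
    return (th + w * (a1 + 2 * a2 + 2 * a3 + a4),
            om + w * (b1 + 2 * b2 + 2 * b3 + b4),
            af + w * (c1 + 2 * c2 + 2 * c3 + c4),
            ae + w * (d1 + 2 * d2 + 2 * d3 + d4))


@njit(cache=True)
def dyn(x, uf, ue, P):
    """State derivative; x = [theta, omega, a_flex, a_ext] (complex128)."""
    d = _dyn_s(x[0], x[1], x[2], x[3], uf, ue, P)
    out = np.empty(4, dtype=np.complex128)
    for k in range(4):
        out[k] = d[k]
    return out


@njit(cache=True)
def rk4_step(x, uf, ue, dt, P):
    y = _rk4_s(x[0], x[1], x[2], x[3], uf, ue, dt, P)
    out = np.empty(4, dtype=np.complex128)
    for k in range(4):
        out[k] = y[k]
    return out


@njit(cache=True)
def trapezoid_step(x, uf, ue, dt, P):
    """Heun (explicit trapezoid) alternative integrator, for sensitivity checks."""
    k1 = dyn(x, uf, ue, P)
    k2 = dyn(x + dt * k1, uf, ue, P)
    return x + 0.5 * dt * (k1 + k2)


@njit(cache=True)
def simulate(u, x0, P, dt):
    """Roll out N = len(u) RK4 steps; returns the (N+1, 4) state trajectory."""
    N = u.shape[0]
    X = np.empty((N + 1, 4))
    th = complex(x0[0]); om = complex(x0[1])
    af = complex(x0[2]); ae = complex(x0[3])
    for k in range(4):
        X[0, k] = x0[k]
    for i in range(N):
        th, om, af, ae = _rk4_s(th, om, af, ae, complex(u[i, 0]),
                                complex(u[i, 1]), dt, P)
        X[i + 1, 0] = th.real
        X[i + 1, 1] = om.real
        X[i + 1, 2] = af.real
        X[i + 1, 3] = ae.real
        th = complex(X[i + 1, 0]); om = complex(X[i + 1, 1])
        af = complex(X[i + 1, 2]); ae = complex(X[i + 1, 3])
    return X


@njit(cache=True)
def _smab(x, s):
    return x * _tanh(x * s)


@njit(cache=True, inline="always")
def _node_cost_s(th, om, af, ae, P, th_t, variant, W_work, s_w, dt):
    """Per-node running cost: squared muscle-length error, plus (augmented)
    the smoothed-absolute mechanical work rate of both muscles times dt."""
    e = P[0] * (th - th_t)
    c = 2.0 * e * e
    if variant == 1.0:
        Ff, Fe = _forces_s(th, om, af, ae, P)
        ld = P[0] * om
        c = c + W_work * dt * (_smab(-ld * Ff, s_w) + _smab(ld * Fe, s_w))
    return c


@njit(cache=True)
def objective_and_gradient(u, x0, P, dt, th_t, w, variant, W_exc, W_work, s_w,
                           include0):
    """Single-shooting objective, terminal-velocity constraint and gradients.

    Forward pass stores the RK4 step-map Jacobians (complex step on the step
    map); the backward pass is the discrete adjoint, run simultaneously for
    the objective and for the terminal velocity h = omega(T).

    Returns (J, dJ/du, h, dh/du, states).
    """
    N = u.shape[0]
    h = CSTEP
    ih = 1j * h
    X = np.empty((N + 1, 4))
    A = np.empty((N, 4, 4))
    B = np.empty((N, 4, 2))
    for k in range(4):
        X[0, k] = x0[k]
    for i in range(N):
        uf = complex(u[i, 0])
        ue = complex(u[i, 1])
        th = complex(X[i, 0]); om = complex(X[i, 1])
        af = complex(X[i, 2]); ae = complex(X[i, 3])
        y = _rk4_s(th, om, af, ae, uf, ue, dt, P)
        for k in range(4):
            X[i + 1, k] = y[k].real
        # step-map Jacobians by complex step, one direction at a time
        y0 = _rk4_s(th + ih, om, af, ae, uf, ue, dt, P)
        y1 = _rk4_s(th, om + ih, af, ae, uf, ue, dt, P)
        y2 = _rk4_s(th, om, af + ih, ae, uf, ue, dt, P)
        y3 = _rk4_s(th, om, af, ae + ih, uf, ue, dt, P)
        for k in range(4):
            A[i, k, 0] = y0[k].imag / h
            A[i, k, 1] = y1[k].imag / h
            A[i, k, 2] = y2[k].imag / h
            A[i, k, 3] = y3[k].imag / h
        yu = _rk4_s(th, om, af, ae, uf + ih, ue, dt, P)
        yv = _rk4_s(th, om, af, ae, uf, ue + ih, dt, P)
        for k in range(4):
            B[i, k, 0] = yu[k].imag / h
            B[i, k, 1] = yv[k].imag / h

    # objective value and node-cost gradients d(cost_i)/dx_i via complex step
    J = 0.0
    dcdx = np.zeros((N + 1, 4))
    for i in range(1, N + 1):
        wt = 1.0 + w if i == N else 1.0
        th = complex(X[i, 0]); om = complex(X[i, 1])
        af = complex(X[i, 2]); ae = complex(X[i, 3])
        c = _node_cost_s(th, om, af, ae, P, th_t, variant, W_work, s_w, dt)
        # the terminal weight applies to the position part only
        e = P[0] * (X[i, 0] - th_t)
        J += c.real + (wt - 1.0) * 2.0 * e * e
        c0 = _node_cost_s(th + ih, om, af, ae, P, th_t, variant, W_work, s_w, dt)
        c1 = _node_cost_s(th, om + ih, af, ae, P, th_t, variant, W_work, s_w, dt)
        c2 = _node_cost_s(th, om, af + ih, ae, P, th_t, variant, W_work, s_w, dt)
        c3 = _node_cost_s(th, om, af, ae + ih, P, th_t, variant, W_work, s_w, dt)
        dcdx[i, 0] = c0.imag / h + (wt - 1.0) * 4.0 * P[0] * e
        dcdx[i, 1] = c1.imag / h
        dcdx[i, 2] = c2.imag / h
        dcdx[i, 3] = c3.imag / h
    if include0 == 1.0:
        e = P[0] * (X[0, 0] - th_t)
        J += 2.0 * e * e
    if variant == 1.0:
        for i in range(N):
            J += W_exc * (u[i, 0] * u[i, 0] + u[i, 1] * u[i, 1])

    gJ = np.zeros((N, 2))
    gh = np.zeros((N, 2))
    lam = dcdx[N].copy()
    nu = np.zeros(4)
    nu[1] = 1.0
    for i in range(N - 1, -1, -1):
        for m in range(2):
            s1 = 0.0
            s2 = 0.0
            for k in range(4):
                s1 += B[i, k, m] * lam[k]
                s2 += B[i, k, m] * nu[k]
            gJ[i, m] = s1
            gh[i, m] = s2
        lam_new = np.zeros(4)
        nu_new = np.zeros(4)
        for j in range(4):
            for k in range(4):
                lam_new[j] += A[i, k, j] * lam[k]
                nu_new[j] += A[i, k, j] * nu[k]
        if i >= 1:
            for j in range(4):
                lam_new[j] += dcdx[i, j]
        lam = lam_new
        nu = nu_new
    if variant == 1.0:
        for i in range(N):
            gJ[i, 0] += 2.0 * W_exc * u[i, 0]
            gJ[i, 1] += 2.0 * W_exc * u[i, 1]
    return J, gJ, X[N, 1], gh, X
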