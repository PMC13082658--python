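"""Smoothed Hill-type muscle curves and the total muscle-force map.

The active force-length curve is a Brown/Loeb-style exponential bump,
``exp(-(((l^b2) - 1)/b3)^b1)``, which peaks at 1 for l = l0 and, with b1 = 2,
is analytic everywhere.  The passive parallel element is a tension-only
exponential spring engaging at the slack length c3; the force-velocity
relation joins the classic Hill concentric hyperbola (zero force at the
maximum shortening rate) to a Katz-style eccentric hyperbola saturating near
``d2_eff``.  Former cusps (passive slack point, concentric/eccentric join)
are smoothed with softplus ramps and tanh sigmoids of gain ``s_smooth``, so
the whole force map has finite derivatives of all orders -- a requirement
for gradient-based trajectory optimisation.

These are the same closed forms evaluated inside the numba simulation
kernel; this module is the vectorised, user-facing seam.  Swapping a curve
here (and in :mod:`agearm._kernel`) is the supported way to explore
alternative Hill formulations.
"""

from __future__ import annotations

import numpy as np

from .params import MuscleParams

__all__ = [
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "scale_eccentric_plateau",
    "muscle_force",
]


def _softplus(x, s):
    x = np.asarray(x, dtype=float)
    t = s * x
    out = np.where(t > 20.0, x + np.exp(-np.clip(t, 20.0, None)) / s,
                   np.where(t < -20.0, np.exp(np.clip(t, None, -20.0)) / s,
                            np.log1p(np.exp(np.clip(t, -20.0, 20.0))) / s))
    return out


def active_force_length(l_norm, b=(2.0, -1.3, 0.53)):
    """Normalized active force vs length (in units of l0); unimodal, peak 1 at 1.

    Raises ``ValueError`` for non-positive lengths.
    """
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise ValueError("l_norm must be positive")
    b1, b2, b3 = b
    q = (l_norm ** b2 - 1.0) / b3
    e = q * q if b1 == 2.0 else np.abs(q) ** b1
    return np.exp(-e)


def passive_force_length(l_norm, c=(0.05, 5.0, 1.0), s_smooth=500.0):
    """Normalized tension-only passive force; ~0 below the slack length c3,
    exponential beyond it, linear in the stiffness scale c1."""
    l_norm = np.asarray(l_norm, dtype=float)
    c1, c2, c3 = c
    if c1 < 0:
        raise ValueError("c1 must be non-negative")
    return c1 * (np.exp(c2 * _softplus(l_norm - c3, s_smooth)) - 1.0)


def force_velocity(v_norm, d=(4.0, 1.4, 30.24), d2_eff=None, s_smooth=500.0):
    """Normalized force vs strain rate (per vmax; positive = lengthening).

    1 at isometric, ~0 at v = -1 (shortening at vmax), monotone increasing,
    saturating near ``d2_eff`` on the eccentric side.
    """
    v = np.asarray(v_norm, dtype=float)
    d1, d2, d3 = d
    if d2_eff is None:
        d2_eff = d2
    vc = -1.0 + _softplus(v + 1.0, s_smooth)
    vc = vc - _softplus(vc - 0.125, s_smooth)
    # tanh ramp (not softplus) so the eccentric argument is exactly 0 at v=0,
    # keeping the isometric normalization f_V(0) = 1 exact
    ve = 0.5 * v * (1.0 + np.tanh(np.clip(s_smooth * v, -30, 30)))
    fc = (1.0 + vc) / (1.0 - d1 * vc)
    fe = (1.0 + d2_eff * d3 * ve) / (1.0 + d3 * ve)
    sig = 0.5 * (1.0 + np.tanh(np.clip(s_smooth * v, -30, 30)))
    return (1.0 - sig) * fc + sig * fe


def scale_eccentric_plateau(Fmax, d2_baseline=1.4, Fmax_baseline=1300.0,
                            rule="preserve_product"):
    """Eccentric plateau for a given Fmax.

    'preserve_product' keeps d2_eff * Fmax at the baseline product so that
    absolute eccentric strength is independent of Fmax; 'literal' returns
    Fmax_baseline / Fmax.
    """
    if Fmax <= 0:
        raise ValueError("Fmax must be positive")
    if rule == "literal":
        return Fmax_baseline / Fmax
    return d2_baseline * Fmax_baseline / Fmax


def muscle_force(a, l_norm, v_norm, p: MuscleParams):
    """Total tensile force (N): Fmax * (a * f_L(l) * f_V(v) + f_P(l))."""
    a = np.asarray(a, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    fl = active_force_length(l_norm, p.b)
    fv = force_velocity(v_norm, p.d, d2_eff=p.d2_eff, s_smooth=p.s_smooth)
    fp = passive_force_length(l_norm, (p.c1, p.c2, p.c3), p.s_smooth)
    return p.Fmax * (a * fl * fv + fp)
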