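"""Scalar performance and coactivation metrics for one solved movement.

``J_RMSE`` converts the accumulated squared muscle-length error into a
root-mean-square positional error in units of the optimal length l0; lower
is better.  The default normalisation is J_RMSE = sqrt(J_SSE / N) / (2 l0),
the per-muscle error of the symmetric pair (both muscles contribute equally
to J_SSE).  Timing metrics use a tolerance band of 1% of the angular
excursion around the target: time-to-target is the first (interpolated)
entry into the band, time-to-stable the earliest time after which the
trajectory never leaves it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import TaskConfig

__all__ = [
    "MetricsRecord",
    "rmse_metric",
    "coactivation",
    "time_to_target",
    "time_to_stable",
    "ballistic_fraction",
    "evaluate_solution",
]


def rmse_metric(J_SSE, N, l0, reading: str = "printed"):
    """Normalized RMS error (units of l0) from the summed squared error.

    'printed' (default): sqrt(J_SSE / N) / (2 l0).
    'per_muscle': sqrt(J_SSE / (2 N)) / l0, i.e. the RMS of one muscle's
    length error; the two readings differ by a factor sqrt(2).
    """
    if J_SSE < 0:
        raise ValueError("J_SSE must be non-negative")
    if reading == "printed":
        return float(np.sqrt(J_SSE / N) / (2.0 * l0))
    if reading == "per_muscle":
        return float(np.sqrt(J_SSE / (2.0 * N)) / l0)
    raise ValueError(f"unknown reading {reading!r}")


def coactivation(a_flex, a_ext, dt):
    """Coactivation time series min(a_flex, a_ext) and its time average
    (trapezoid rule over the nodes)."""
    a_flex = np.asarray(a_flex, dtype=float)
    a_ext = np.asarray(a_ext, dtype=float)
    ac = np.minimum(a_flex, a_ext)
    T = dt * (len(ac) - 1)
    mean = float(np.trapezoid(ac, dx=dt) / T) if T > 0 else float(ac[0])
    return ac, mean


def _band_entry_time(err, t, tol):
    """First time |error| <= tol, linearly interpolated; None if never."""
    inside = err <= tol
    if inside[0]:
        return 0.0
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        return None
    i = idx[0]
    frac = (err[i - 1] - tol) / (err[i - 1] - err[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def time_to_target(theta, task: TaskConfig, tol_frac: float = 0.01):
    """First time the joint angle enters the target tolerance band; T if never."""
    theta = np.asarray(theta, dtype=float)
    t = np.arange(len(theta)) * task.dt
    tol = tol_frac * task.excursion
    err = np.abs(theta - task.theta_target)
    tt = _band_entry_time(err, t, tol)
    return task.T if tt is None else tt


def time_to_stable(theta, task: TaskConfig, tol_frac: float = 0.01):
    """Earliest time after which the angle never leaves the tolerance band."""
    theta = np.asarray(theta, dtype=float)
    t = np.arange(len(theta)) * task.dt
    tol = tol_frac * task.excursion
    err = np.abs(theta - task.theta_target)
    outside = np.flatnonzero(err > tol)
    if outside.size == 0:
        return 0.0
    i = outside[-1]  # last node outside the band
    if i == len(theta) - 1:
        return task.T
    frac = (err[i] - tol) / (err[i] - err[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def ballistic_fraction(theta, task: TaskConfig, t_split):
    """Fraction of the summed squared error accrued at nodes with t <= t_split.

    ``t_split`` marks the end of the ballistic phase; the standard choice is
    the time to the stable point T_S (the movement is ballistic until it has
    settled), with the time to target T_T as a stricter alternative.  Because
    both muscles' length errors are proportional to the angular error, the
    ratio is computed directly on squared angular errors.
    """
    theta = np.asarray(theta, dtype=float)
    T_T = t_split
    t = np.arange(len(theta)) * task.dt
    start = 0 if task.include_initial_node else 1
    sq = (theta - task.theta_target) ** 2
    total = float(np.sum(sq[start:]))
    if total == 0:
        return 1.0
    early = float(np.sum(sq[start:][t[start:] <= T_T]))
    return min(early / total, 1.0)  # masked summation can round past 1


def excitation_bursts(u, threshold: float = 0.05):
    """Contiguous bursts (start, end) of node indices where u > threshold
    (end exclusive).  Used to classify triphasic excitation patterns."""
    u = np.asarray(u, dtype=float)
    above = u > threshold
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(u))
    return list(zip(starts, ends))


def onset_time(series, dt, threshold: float = 0.01):
    """First node time at which the series exceeds the threshold; None if never."""
    idx = np.flatnonzero(np.asarray(series, dtype=float) > threshold)
    return None if idx.size == 0 else float(idx[0] * dt)


def offset_time(series, dt, threshold: float = 0.01):
    """Last node time at which the series still exceeds the threshold,
    scanning from the start (i.e. end of the first supra-threshold run)."""
    s = np.asarray(series, dtype=float)
    idx = np.flatnonzero(s > threshold)
    if idx.size == 0:
        return None
    # end of the first contiguous run
    breaks = np.flatnonzero(np.diff(idx) > 1)
    last = idx[breaks[0]] if breaks.size else idx[-1]
    return float(last * dt)


@dataclass
class MetricsRecord:
    """All scalar outcomes for one optimal solution."""

    J_RMSE: float       # units of l0
    a_c_mean: float     # mean coactivation, dimensionless
    T_T: float          # time to target, s
    T_S: float          # time to stable point, s
    J_RMSE_rel: float   # ballistic-phase fraction of the error, in [0, 1]

    def to_dict(self) -> dict:
        return {
            "J_RMSE": self.J_RMSE, "a_c_mean": self.a_c_mean,
            "T_T": self.T_T, "T_S": self.T_S, "J_RMSE_rel": self.J_RMSE_rel,
        }


def evaluate_solution(sol, tol_frac: float = 0.01,
                      reading: str = "printed") -> MetricsRecord:
    """Compute the full metrics record from an :class:`OptimalSolution`."""
    task = sol.task
    theta = sol.states[:, 0]
    J_RMSE = rmse_metric(sol.J_SSE, task.N, sol.geometry.l0, reading=reading)
    _, ac_mean = coactivation(sol.states[:, 2], sol.states[:, 3], task.dt)
    tt = time_to_target(theta, task, tol_frac)
    ts = time_to_stable(theta, task, tol_frac)
    rel = ballistic_fraction(theta, task, ts)
    return MetricsRecord(J_RMSE=J_RMSE, a_c_mean=ac_mean, T_T=tt, T_S=ts,
                         J_RMSE_rel=rel)
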