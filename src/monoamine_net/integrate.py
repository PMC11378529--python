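"""Numerical integration of the circuit and settled-state extraction.

Simulations use scipy's variable-order, variable-step BDF scheme.  A run is
halted (and flagged) as soon as any area leaves the physically valid box
[0, F_max]; a small slack below zero tolerates solver-level undershoot of an
initial condition sitting exactly on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import F_MAX_HZ
from .model import AREAS, ModelMatrices, rhs

__all__ = ["Trajectory", "TrajectoryError", "integrate", "steady_state", "settle"]

DEFAULT_T_END = 0.5
DEFAULT_TRANSIENT_CUT = 0.1
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class TrajectoryError(RuntimeError):
    """Raised when a settled state is requested from an aborted trajectory."""


@dataclass
class Trajectory:
    """Time-stamped solution of one simulation.

    ``y`` has one row per area in the canonical ordering; ``stopped`` is set
    iff integration was aborted, with ``reason`` recording why.
    """

    t: np.ndarray
    y: np.ndarray
    stopped: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        self.t = np.atleast_1d(np.asarray(self.t, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.y.shape[0] != len(AREAS) or self.y.shape[1] != self.t.size:
            raise ValueError("trajectory shape mismatch")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"time": self.t})
        for i, a in enumerate(AREAS):
            frame[a] = self.y[i]
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def integrate(
    m: ModelMatrices,
    y0: np.ndarray | None = None,
    t0: float = 0.0,
    t_end: float = DEFAULT_T_END,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    fmax: float = F_MAX_HZ,
    lower_slack: float = 1e-6,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the model from ``y0`` (default: all areas silent) over
    [t0, t_end].

    Solver failures never propagate: they return a flagged trajectory, as
    does a crossing of the physically-valid box (detected by root-finding
    events on min(y) and F_max - max(y)).
    """
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    y0 = np.zeros(len(AREAS)) if y0 is None else np.asarray(y0, dtype=float)
    if not (np.all(np.isfinite(y0)) and np.all(y0 >= 0.0) and np.all(y0 <= fmax)):
        raise ValueError("y0 must be physically valid (all areas in [0, fmax])")

    def below(t, y):
        return float(np.min(y) + lower_slack)

    def above(t, y):
        return float(fmax - np.max(y))

    below.terminal = True
    below.direction = -1
    above.terminal = True
    above.direction = -1

    def fun(t, y):
        return rhs(y, m)

    def jac(t, y):
        return m.A + 2.0 * m.C * y[None, :]

    try:
        sol = solve_ivp(
            fun,
            (t0, t_end),
            y0,
            method=method,
            jac=jac,
            rtol=rtol,
            atol=atol,
            events=(below, above),
            dense_output=False,
        )
    except Exception as exc:  # pragma: no cover - defensive
        return Trajectory(np.array([t0]), y0[:, None], stopped=True, reason=f"solver error: {exc}")

    if sol.status == 1:
        which = "below zero" if len(sol.t_events[0]) else "above F_max"
        return Trajectory(sol.t, sol.y, stopped=True, reason=f"nonphysical state ({which})")
    if sol.status != 0:
        return Trajectory(sol.t, sol.y, stopped=True, reason=f"solver failure: {sol.message}")
    return Trajectory(sol.t, sol.y)


def steady_state(
    traj: Trajectory,
    transient_cut: float = DEFAULT_TRANSIENT_CUT,
    mode: str = "mean",
) -> np.ndarray:
    """Settled per-area value of a completed trajectory.

    By default the mean of all samples past the transient cut (robust to
    residual ripple); ``mode="last"`` returns the final sample instead.
    """
    if traj.stopped:
        raise TrajectoryError(f"trajectory was aborted: {traj.reason}")
    if mode == "last":
        return traj.y[:, -1].copy()
    if mode != "mean":
        raise ValueError("mode must be 'mean' or 'last'")
    mask = traj.t >= traj.t[0] + transient_cut
    if not np.any(mask):
        raise ValueError("no samples past the transient cut")
    return traj.y[:, mask].mean(axis=1)


def settle(m: ModelMatrices, **kwargs) -> np.ndarray:
    """Integrate from silence with defaults and return the settled state."""
    cut = kwargs.pop("transient_cut", DEFAULT_TRANSIENT_CUT)
    mode = kwargs.pop("mode", "mean")
    return steady_state(integrate(m, **kwargs), transient_cut=cut, mode=mode)
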