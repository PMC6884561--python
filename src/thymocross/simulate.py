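"""DDE simulation of a model topology plus the irradiation observation layer.

The integrator is a method-of-steps Dormand-Prince RK45 (see ``_dde``); the
state starts at the post-irradiation jump n(0) = p * n_tot0 with constant
pre-history n_tot0, and the observable trajectory adds the exponentially
decaying irradiation-killed pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _dde
from .params import (
    AlternativeParams,
    CoarseParams,
    COARSE_TYPES,
    DETAILED_TYPES,
    DetailedParams,
    IrradiationModel,
)

__all__ = ["SimulationSpec", "Trajectory", "SimulationError", "simulate", "observe"]


class SimulationError(RuntimeError):
    """Raised when the DDE solver fails (step underflow, non-finite state...)."""


_STATUS_MSG = {
    _dde.STEP_UNDERFLOW: "step-size underflow",
    _dde.MAX_STEPS_EXCEEDED: "maximum step count exceeded",
    _dde.NONFINITE_STATE: "non-finite state",
}


@dataclass
class Trajectory:
    """Simulated populations on a time grid.

    ``n`` are the surviving/regenerating cells, ``n_x`` the irradiation-killed
    pool, ``n_tot = n + n_x`` the observable counts; arrays have shape
    (len(t), number of compartments).
    """

    cell_types: tuple
    t: np.ndarray
    n: np.ndarray
    n_x: np.ndarray

    @property
    def n_tot(self) -> np.ndarray:
        return self.n + self.n_x

    def column(self, cell_type, which: str = "n_tot") -> np.ndarray:
        j = [str(c) for c in self.cell_types].index(str(cell_type))
        return getattr(self, which)[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per grid point per compartment."""
        rows = []
        for j, ct in enumerate(self.cell_types):
            rows.append(pd.DataFrame({
                "day": self.t,
                "cell_type": str(ct),
                "n": self.n[:, j],
                "n_x": self.n_x[:, j],
                "n_tot": self.n_tot[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class SimulationSpec:
    """Everything needed to integrate one topology once."""

    params: CoarseParams | DetailedParams | AlternativeParams
    irr: IrradiationModel
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 49.0, 491))
    rtol: float = 1e-8
    atol: float = 1e-2          # cells; populations span ~1e3-1e8
    max_step: float = np.inf    # additionally capped at the smallest positive delay
    disc_order: int = 3         # propagation order of delay discontinuities

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 1 or self.grid.size == 0:
            raise ValueError("time grid must be a non-empty 1-D array")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.grid[0] < 0:
            raise ValueError("time grid must start at t >= 0")


def _topology_arrays(params):
    """(topo id, params array, extras, delays, lag component indices)."""
    if isinstance(params, AlternativeParams):
        p = params.base.to_array()
        return (int(params.variant), p, params.extras_array(),
                np.array([p[7], p[18]]), np.array([2, 1], dtype=np.int64))
    if isinstance(params, DetailedParams):
        p = params.to_array()
        return (_dde.DETAILED, p, np.zeros(4),
                np.array([p[17], 0.0]), np.array([5, 0], dtype=np.int64))
    if isinstance(params, CoarseParams):
        p = params.to_array()
        return (_dde.COARSE, p, np.zeros(4),
                np.array([p[7], p[18]]), np.array([2, 1], dtype=np.int64))
    raise TypeError(f"unsupported parameter set type: {type(params)!r}")


def discontinuity_times(delays, t_end: float, order: int = 3) -> np.ndarray:
    """Times k1*tau2 + k2*taum (k1 + k2 <= order) where derivative jumps propagate."""
    taus = [d for d in np.atleast_1d(delays) if d > 0]
    pts = set()
    if len(taus) == 1:
        for k in range(1, order + 1):
            pts.add(k * taus[0])
    elif len(taus) == 2:
        for k1 in range(order + 1):
            for k2 in range(order + 1 - k1):
                if k1 + k2 > 0:
                    pts.add(k1 * taus[0] + k2 * taus[1])
    return np.array(sorted(p for p in pts if 0 < p < t_end), dtype=np.float64)


def _integrate_n(params, irr: IrradiationModel, t_eval: np.ndarray,
                 rtol: float, atol: float, max_step: float,
                 disc_order: int) -> np.ndarray:
    """Surviving-pool trajectory n(t) at t_eval; raises SimulationError on failure."""
    topo, p, ex, delays, lag_idx = _topology_arrays(params)
    t_end = float(t_eval[-1])
    y0 = irr.survivors0()
    hist = irr.n_tot0.astype(np.float64)
    breaks = discontinuity_times(delays, t_end, disc_order)
    ms = np.inf if max_step is None else float(max_step)
    for max_steps in (8192, 131072):
        y, status = _dde._integrate(topo, p, ex, y0, hist, delays, lag_idx,
                                    t_end, t_eval, rtol, atol, ms, breaks,
                                    max_steps)
        if status != _dde.MAX_STEPS_EXCEEDED:
            break
    if status != _dde.OK:
        raise SimulationError(
            f"DDE integration failed: {_STATUS_MSG.get(status, status)} "
            f"(topology {topo}, t_end {t_end})")
    return y


def simulate(spec: SimulationSpec) -> Trajectory:
    """Integrate the model and return n, n_x and n_tot on the requested grid."""
    if isinstance(spec.params, DetailedParams):
        cts = DETAILED_TYPES
    else:
        cts = COARSE_TYPES
    if tuple(spec.irr.cell_types) != tuple(cts):
        raise ValueError(
            f"irradiation model compartments {spec.irr.cell_types} do not match "
            f"the topology's state vector {cts}")
    n = _integrate_n(spec.params, spec.irr, spec.grid, spec.rtol, spec.atol,
                     spec.max_step, spec.disc_order)
    n_x = spec.irr.decayed_matrix(spec.grid)
    return Trajectory(cell_types=cts, t=spec.grid, n=n, n_x=n_x)


def observe(traj: Trajectory, days) -> pd.DataFrame:
    """Interpolated observable counts at the requested days (tidy table).

    Uses linear interpolation on the trajectory grid; requests outside the
    simulated span are rejected.
    """
    days = np.asarray(days, dtype=float)
    if days.min() < traj.t[0] - 1e-12 or days.max() > traj.t[-1] + 1e-12:
        raise ValueError(
            f"requested days [{days.min()}, {days.max()}] extend beyond the "
            f"trajectory span [{traj.t[0]}, {traj.t[-1]}]")
    rows = []
    for j, ct in enumerate(traj.cell_types):
        rows.append(pd.DataFrame({
            "day": days,
            "cell_type": str(ct),
            "n_tot": np.interp(days, traj.t, traj.n_tot[:, j]),
        }))
    return pd.concat(rows, ignore_index=True)
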