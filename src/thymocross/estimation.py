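"""Log-space least-squares fitting of any model topology to count data.

The objective is the sum over every observed replicate slot of the squared
difference between log observed and log simulated total counts, minimized by
the Trust Region Reflective algorithm (scipy ``least_squares``).  To condition
the search, each parameter theta is decomposed as theta = theta_c * theta_p
with theta_p a fixed power of ten (the one nearest the initial guess); the
optimizer works on the coefficient theta_c.  Search ranges follow the study's
rule: fraction-type parameters (survival fractions and transfer fractions) on
[0, 1], every other free parameter within a factor of ten of its initial
guess.  The kinetic parameters, the pre-irradiation sizes, the survival
fractions and the dying-pool decay rates can all be freed simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import _dde
from .data import validate_counts
from .params import (
    AlternativeParams,
    CoarseParams,
    COARSE_TYPES,
    DETAILED_TYPES,
    DetailedParams,
    EXTRA_NAMES,
    FRACTION_PARAMS,
    IrradiationModel,
    Topology,
)
from .simulate import SimulationSpec, Trajectory, discontinuity_times, simulate

__all__ = [
    "FitProblem",
    "FitResult",
    "TwoStageFitResult",
    "SubstitutionResult",
    "objective",
    "fit",
    "fit_detailed_two_stage",
    "substitute_and_resimulate",
    "values_to_params",
    "values_to_irradiation",
    "default_values",
]

#: parameters shared between the coarse and the detailed model (fixed to the
#: coarse estimates during two-stage estimation)
SHARED_DETAILED = ("phi1", "theta2", "K2", "mu2", "tau2", "phic", "deltac")

_PENALTY_RESIDUAL = 1.0e3  # per-slot residual reported when a simulation fails


def _cell_types_for(topology: Topology):
    if topology in (Topology.DETAILED, Topology.DETAILED_VERBATIM):
        return DETAILED_TYPES
    return COARSE_TYPES


def _kinetic_names(topology: Topology):
    if topology in (Topology.DETAILED, Topology.DETAILED_VERBATIM):
        return DetailedParams.names()
    names = CoarseParams.names()
    if topology in (Topology.M1_NO_MTEC_SELFSUPPRESSION, Topology.M2_DN_TO_MTEC,
                    Topology.M3_CTEC_BOOSTS_DP, Topology.M4_DP_TO_CTEC):
        return names + list(EXTRA_NAMES)
    return names


def values_to_params(topology: Topology, values: Mapping[str, float]):
    """Build the parameter object of ``topology`` from a flat value mapping."""
    topology = Topology(topology)
    if topology in (Topology.DETAILED, Topology.DETAILED_VERBATIM):
        return DetailedParams(**{n: values[n] for n in DetailedParams.names()})
    base = CoarseParams(**{n: values[n] for n in CoarseParams.names()})
    if topology == Topology.COARSE:
        return base
    extras = {n: values.get(n, 0.0) for n in EXTRA_NAMES}
    return AlternativeParams(variant=topology, base=base, **extras)


def values_to_irradiation(topology: Topology, values: Mapping[str, float]) -> IrradiationModel:
    return IrradiationModel.from_flat_dict(_cell_types_for(Topology(topology)), values)


def default_values(topology: Topology) -> dict[str, float]:
    """Truth template (kinetics + irradiation) of the shipped default regime."""
    from .defaults import (
        default_coarse_truth,
        default_detailed_irradiation,
        default_detailed_truth,
        default_irradiation,
    )

    topology = Topology(topology)
    if topology in (Topology.DETAILED, Topology.DETAILED_VERBATIM):
        vals = default_detailed_truth().to_dict()
        vals.update(default_detailed_irradiation().to_dict())
        return vals
    vals = default_coarse_truth().to_dict()
    if topology != Topology.COARSE:
        vals.update({n: 0.0 for n in EXTRA_NAMES})
    vals.update(default_irradiation().to_dict())
    return vals


def _nearest_pow10(x: float) -> float:
    if x <= 0:
        return 1.0
    return 10.0 ** round(np.log10(x))


@dataclass
class FitProblem:
    """A dataset, a topology, and the free-parameter specification.

    ``values`` is the complete flat parameter template (kinetic parameters
    plus, per compartment, ``ntot0_*``, ``p_*`` and ``omega_*``); ``free``
    lists the names the optimizer may move, all others stay fixed.  The
    initial ``guess`` defaults to the template values.  ``replicate_mode``
    selects whether every replicate contributes its own residual (default;
    reduces to the plain per-time-point objective when replicates are one)
    or replicates are averaged per day on the log scale first.
    """

    topology: Topology
    data: pd.DataFrame
    values: dict[str, float]
    free: Sequence[str]
    guess: dict[str, float] = field(default_factory=dict)
    theta_p: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple] = field(default_factory=dict)
    replicate_mode: str = "replicates"
    rtol: float = 1e-6
    atol: float = 1e-2
    disc_order: int = 3

    def __post_init__(self) -> None:
        self.topology = Topology(self.topology)
        self.data = validate_counts(self.data)
        self.free = list(self.free)
        known = set(_kinetic_names(self.topology))
        for ct in _cell_types_for(self.topology):
            known |= {f"ntot0_{ct.value}", f"p_{ct.value}", f"omega_{ct.value}"}
        missing = known - set(self.values)
        if missing:
            raise ValueError(f"values template is missing entries: {sorted(missing)}")
        unknown = [n for n in self.free if n not in known]
        if unknown:
            raise ValueError(f"unknown free parameter(s): {unknown}")
        self.values = {k: float(v) for k, v in self.values.items()}
        guess = dict(self.guess)
        self.guess = {n: float(guess.get(n, self.values[n])) for n in self.free}
        theta_p = dict(self.theta_p)
        self.theta_p = {}
        for n in self.free:
            if n in theta_p:
                self.theta_p[n] = float(theta_p[n])
            elif n in FRACTION_PARAMS:
                self.theta_p[n] = 1.0
            else:
                self.theta_p[n] = _nearest_pow10(self.guess[n])
        bounds = dict(self.bounds)
        self.bounds = {}
        for n in self.free:
            if n in bounds:
                self.bounds[n] = (float(bounds[n][0]), float(bounds[n][1]))
            elif n in FRACTION_PARAMS:
                self.bounds[n] = (0.0, 1.0)
            else:
                g = self.guess[n]
                if g <= 0:
                    raise ValueError(
                        f"free parameter {n} needs a strictly positive guess "
                        "for the factor-of-ten search range")
                self.bounds[n] = (0.1 * g, 10.0 * g)
        if self.replicate_mode not in ("replicates", "daymean"):
            raise ValueError("replicate_mode must be 'replicates' or 'daymean'")
        self._prepare_observations()

    # -- observation layout -------------------------------------------------
    def _prepare_observations(self) -> None:
        cts = [ct.value for ct in _cell_types_for(self.topology)]
        df = self.data[self.data["cell_type"].isin(cts)]
        if df.empty:
            raise ValueError(f"dataset contains no rows for compartments {cts}")
        if self.replicate_mode == "daymean":
            df = (df.assign(logN=np.log(df["count"]))
                    .groupby(["day", "cell_type"], as_index=False)["logN"].mean())
        else:
            df = df.assign(logN=np.log(df["count"]))
        days = np.unique(df["day"].to_numpy(dtype=float))
        day_pos = {d: i for i, d in enumerate(days)}
        type_pos = {c: j for j, c in enumerate(cts)}
        self._obs_days = days
        self._obs_day_idx = df["day"].map(day_pos).to_numpy(dtype=np.int64)
        self._obs_type_idx = df["cell_type"].map(type_pos).to_numpy(dtype=np.int64)
        self._obs_logN = df["logN"].to_numpy(dtype=np.float64)
        self._cts = cts

    @property
    def n_residuals(self) -> int:
        return self._obs_logN.size

    # -- theta_c packing ----------------------------------------------------
    def theta_c0(self) -> np.ndarray:
        return np.array([self.guess[n] / self.theta_p[n] for n in self.free])

    def theta_c_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] / self.theta_p[n] for n in self.free])
        hi = np.array([self.bounds[n][1] / self.theta_p[n] for n in self.free])
        return lo, hi

    def values_from_theta_c(self, theta_c: np.ndarray) -> dict[str, float]:
        vals = dict(self.values)
        for n, c in zip(self.free, np.asarray(theta_c, dtype=float)):
            vals[n] = c * self.theta_p[n]
        return vals

    # -- fast simulation of the observables ---------------------------------
    def _sim_arrays(self, vals: Mapping[str, float]):
        topo = int(self.topology)
        if topo in (int(Topology.DETAILED), int(Topology.DETAILED_VERBATIM)):
            p = np.array([vals[n] for n in DetailedParams.names()])
            ex = np.zeros(4)
            delays = np.array([p[17], 0.0])
            lag_idx = np.array([5, 0], dtype=np.int64)
        else:
            p = np.array([vals[n] for n in CoarseParams.names()])
            ex = np.array([vals.get(n, 0.0) for n in EXTRA_NAMES])
            delays = np.array([p[7], p[18]])
            lag_idx = np.array([2, 1], dtype=np.int64)
        cts = self._cts
        ntot0 = np.array([vals[f"ntot0_{c}"] for c in cts])
        psurv = np.array([vals[f"p_{c}"] for c in cts])
        omega = np.array([vals[f"omega_{c}"] for c in cts])
        return topo, p, ex, delays, lag_idx, ntot0, psurv, omega

    def simulated_ntot(self, vals: Mapping[str, float]) -> np.ndarray | None:
        """n_tot at the observation days (days x compartments); None on failure."""
        topo, p, ex, delays, lag_idx, ntot0, psurv, omega = self._sim_arrays(vals)
        days = self._obs_days
        t_end = float(days[-1])
        breaks = discontinuity_times(delays, t_end, self.disc_order)
        y, status = _dde._integrate(topo, p, ex, psurv * ntot0, ntot0, delays,
                                    lag_idx, t_end, days, self.rtol, self.atol,
                                    np.inf, breaks, 8192)
        if status != _dde.OK:
            return None
        n_x = ntot0 * (1.0 - psurv) * np.exp(-omega * days[:, None])
        return y + n_x

    def residuals(self, theta_c: np.ndarray) -> np.ndarray:
        """Log residuals per observation slot; a flat penalty on solver failure."""
        vals = self.values_from_theta_c(theta_c)
        ntot = self.simulated_ntot(vals)
        if ntot is None or np.any(ntot <= 0) or not np.all(np.isfinite(ntot)):
            return np.full(self.n_residuals, _PENALTY_RESIDUAL)
        lognt = np.log(ntot)
        return lognt[self._obs_day_idx, self._obs_type_idx] - self._obs_logN

    def sigma2(self, vals: Mapping[str, float]) -> dict[str, float]:
        """Per-compartment residual variances, denominator m - 1."""
        ntot = self.simulated_ntot(vals)
        if ntot is None:
            raise RuntimeError("simulation failed at the supplied parameter values")
        res = np.log(ntot)[self._obs_day_idx, self._obs_type_idx] - self._obs_logN
        out = {}
        for j, c in enumerate(self._cts):
            r = res[self._obs_type_idx == j]
            out[c] = float(np.sum(r**2) / (r.size - 1)) if r.size > 1 else 0.0
        return out

    def with_data(self, data: pd.DataFrame) -> "FitProblem":
        """Same problem on a different dataset (used by the bootstrap)."""
        return dc_replace(self, data=data, guess=dict(self.guess),
                          theta_p=dict(self.theta_p), bounds=dict(self.bounds))


def objective(theta_c: np.ndarray, problem: FitProblem) -> float:
    """Log-scale sum of squared residuals at the given coefficient vector."""
    r = problem.residuals(np.asarray(theta_c, dtype=float))
    return float(np.dot(r, r))


@dataclass
class FitResult:
    """Point estimate and diagnostics of one least-squares fit."""

    problem: FitProblem
    values: dict[str, float]          # full parameter set at the optimum
    theta_c: np.ndarray
    objective: float
    sigma2: dict[str, float]
    success: bool
    status: int
    nfev: int
    message: str

    @property
    def params(self):
        return values_to_params(self.problem.topology, self.values)

    @property
    def irr(self) -> IrradiationModel:
        return values_to_irradiation(self.problem.topology, self.values)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"parameter": n, "estimate": self.values[n],
             "guess": self.problem.guess[n],
             "lower": self.problem.bounds[n][0],
             "upper": self.problem.bounds[n][1]}
            for n in self.problem.free
        ]
        return pd.DataFrame(rows)


def fit(problem: FitProblem, seed=None, *, ftol: float = 1e-10,
        xtol: float = 1e-10, gtol: float = 1e-10,
        max_nfev: int | None = None) -> FitResult:
    """Bounded Trust Region Reflective minimization of the log-SSE objective.

    Deterministic given the problem (``seed`` is accepted for interface
    uniformity; the optimizer itself is deterministic).  On non-convergence
    the best point found is returned with ``success=False``.
    """
    del seed  # deterministic optimizer
    x0 = problem.theta_c0()
    lo, hi = problem.theta_c_bounds()
    x0 = np.clip(x0, lo, hi)
    res = least_squares(problem.residuals, x0, bounds=(lo, hi), method="trf",
                        ftol=ftol, xtol=xtol, gtol=gtol, max_nfev=max_nfev)
    vals = problem.values_from_theta_c(res.x)
    try:
        sig2 = problem.sigma2(vals)
    except RuntimeError:
        sig2 = {c: float("nan") for c in problem._cts}
    return FitResult(
        problem=problem, values=vals, theta_c=res.x.copy(),
        objective=float(2.0 * res.cost), sigma2=sig2,
        success=bool(res.success and res.status > 0),
        status=int(res.status), nfev=int(res.nfev), message=str(res.message),
    )


@dataclass
class TwoStageFitResult:
    """Both stages of the detailed-model estimation."""

    stage1: FitResult   # shared parameters fixed to the coarse estimates
    stage2: FitResult   # DN influx phi1 additionally freed

    @property
    def final(self) -> FitResult:
        return self.stage2


def fit_detailed_two_stage(problem: FitProblem, coarse_result: FitResult,
                           **fit_kw) -> TwoStageFitResult:
    """Two-stage estimation of the detailed DN1-DN4 model.

    Stage 1 fixes the parameters shared with the coarse model (phi1 and the
    DP/cTEC parameters) to the coarse-fit estimates and fits the DN-stage
    parameters.  Stage 2 re-frees phi1 (with the guess supplied by
    ``problem``), which is how a DN influx far smaller than the coarse
    estimate can be recovered; both results are returned.
    """
    if Topology(problem.topology) not in (Topology.DETAILED, Topology.DETAILED_VERBATIM):
        raise ValueError("two-stage estimation applies to the detailed topology")
    shared_vals = {n: coarse_result.values[n] for n in SHARED_DETAILED}

    vals1 = dict(problem.values)
    vals1.update(shared_vals)
    free1 = [n for n in problem.free if n not in SHARED_DETAILED]
    p1 = FitProblem(topology=problem.topology, data=problem.data, values=vals1,
                    free=free1,
                    guess={n: problem.guess[n] for n in free1},
                    theta_p={n: problem.theta_p[n] for n in free1},
                    bounds={n: problem.bounds[n] for n in free1},
                    replicate_mode=problem.replicate_mode, rtol=problem.rtol,
                    atol=problem.atol, disc_order=problem.disc_order)
    r1 = fit(p1, **fit_kw)

    vals2 = dict(r1.values)
    free2 = free1 + ["phi1"]
    guess2 = {n: r1.values[n] for n in free1}
    guess2["phi1"] = problem.guess.get("phi1", problem.values["phi1"])
    bounds2 = {n: p1.bounds[n] for n in free1}
    if "phi1" in problem.bounds:
        bounds2["phi1"] = problem.bounds["phi1"]
    p2 = FitProblem(topology=problem.topology, data=problem.data, values=vals2,
                    free=free2, guess=guess2, bounds=bounds2,
                    replicate_mode=problem.replicate_mode, rtol=problem.rtol,
                    atol=problem.atol, disc_order=problem.disc_order)
    r2 = fit(p2, **fit_kw)
    return TwoStageFitResult(stage1=r1, stage2=r2)


@dataclass
class SubstitutionResult:
    """Re-simulation under parameter overrides, with a change report."""

    trajectory: Trajectory
    baseline: Trajectory
    max_rel_change: dict[str, float]

    def unaffected(self, threshold: float = 0.05) -> bool:
        """True when no compartment moved more than ``threshold`` (relative)."""
        return max(self.max_rel_change.values()) < threshold


def substitute_and_resimulate(result: FitResult, overrides: Mapping[str, float],
                              grid=None) -> SubstitutionResult:
    """Simulate the fitted model with some parameters replaced.

    Reports, per compartment, the maximum relative change of the observable
    trajectory versus the unmodified fit.
    """
    unknown = [k for k in overrides if k not in result.values]
    if unknown:
        raise KeyError(f"override(s) reference unknown parameters: {unknown}")
    if grid is None:
        t_end = float(result.problem._obs_days[-1])
        grid = np.linspace(0.0, t_end, max(int(t_end * 10) + 1, 101))
    vals = dict(result.values)
    vals.update({k: float(v) for k, v in overrides.items()})
    topo = result.problem.topology
    irr = values_to_irradiation(topo, vals)
    base = simulate(SimulationSpec(params=result.params, irr=result.irr, grid=grid))
    sub = simulate(SimulationSpec(params=values_to_params(topo, vals), irr=irr, grid=grid))
    change = {}
    for j, ct in enumerate(base.cell_types):
        b = base.n_tot[:, j]
        change[str(ct)] = float(np.max(np.abs(sub.n_tot[:, j] - b) / np.abs(b)))
    return SubstitutionResult(trajectory=sub, baseline=base, max_rel_change=change)
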