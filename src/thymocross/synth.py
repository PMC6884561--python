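"""Synthetic count datasets with the design of the irradiation-recovery study.

The generator reproduces the study's structure without its raw data: the
13-day sampling schedule with per-day replicate numbers (separate for
thymocytes and TECs), multiplicative log-normal measurement noise around the
deterministic trajectory, unperturbed baseline samples at the steady state,
the DN non-T-lineage contamination correction, and the reconstruction of
DN1-DN4 stage counts from stage proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import validate_counts
from .params import CellType, IrradiationModel
from .simulate import SimulationSpec, simulate

__all__ = [
    "StudyDesign",
    "NoiseModel",
    "generate",
    "generate_baseline",
    "apply_dn_contamination_correction",
    "inflate_dn_contamination",
    "estimate_dn_subpop_counts",
    "DN_CONTAMINATION_PERCENT",
]

#: average percentage of non-T-lineage cells in the DN gate at steady state
DN_CONTAMINATION_PERCENT = 16.6

#: sampling days of the recovery time course
_DAYS = (0, 1, 4, 7, 9, 11, 12, 13, 14, 15, 17, 19, 49)
#: mice sampled per day for thymocyte counts
_THY_REPS = (4, 6, 3, 3, 3, 3, 2, 3, 3, 3, 3, 6, 3)
#: mice sampled per day for TEC counts
_TEC_REPS = (4, 6, 3, 6, 3, 3, 2, 3, 6, 3, 3, 6, 3)

_THYMOCYTES = frozenset({"DN", "DP", "SP4", "DN1", "DN2", "DN3", "DN4"})
_TECS = frozenset({"cTEC", "mTEC"})


@dataclass
class StudyDesign:
    """Sampling schedule and replicate numbers of the recovery experiment."""

    days: tuple = _DAYS
    thymocyte_replicates: tuple = _THY_REPS
    tec_replicates: tuple = _TEC_REPS
    baseline_n_thymocytes: int = 15
    baseline_n_tecs: int = 16

    def __post_init__(self) -> None:
        self.days = tuple(float(d) for d in self.days)
        self.thymocyte_replicates = tuple(int(r) for r in self.thymocyte_replicates)
        self.tec_replicates = tuple(int(r) for r in self.tec_replicates)
        if not (len(self.days) == len(self.thymocyte_replicates) == len(self.tec_replicates)):
            raise ValueError("day and replicate lists must have equal length")
        if min(self.thymocyte_replicates + self.tec_replicates) < 1:
            raise ValueError("replicate counts must be >= 1")

    def replicates_for(self, cell_type) -> tuple:
        name = str(CellType(str(cell_type)).value)
        if name in _THYMOCYTES:
            return self.thymocyte_replicates
        if name in _TECS:
            return self.tec_replicates
        raise ValueError(f"unknown compartment {cell_type!r}")


@dataclass
class NoiseModel:
    """Log-scale Gaussian measurement noise, per cell type.

    ``sigma`` is either a single log-standard-deviation applied to every
    compartment or a mapping cell type -> sigma.  The default 0.2 gives
    roughly +/-20% multiplicative scatter, matching the visual replicate
    spread of the published time courses (which do not report a variance).
    """

    sigma: float | Mapping = 0.2

    def sigma_for(self, cell_type) -> float:
        if isinstance(self.sigma, Mapping):
            s = float(self.sigma[str(cell_type)])
        else:
            s = float(self.sigma)
        if s < 0:
            raise ValueError("noise sigma must be >= 0")
        return s


def generate(params, irr: IrradiationModel, design: StudyDesign | None = None,
             noise: NoiseModel | None = None, seed=None,
             rtol: float = 1e-8, atol: float = 1e-2) -> pd.DataFrame:
    """Simulate the truth and draw replicate counts on the study design.

    Each (day, cell type, replicate) slot receives
    ``count = n_tot(day) * exp(eps)`` with ``eps ~ N(0, sigma_i^2)``,
    independent across slots; deterministic given ``seed``.
    """
    design = design or StudyDesign()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    days = np.asarray(design.days, dtype=float)
    traj = simulate(SimulationSpec(params=params, irr=irr, grid=days,
                                   rtol=rtol, atol=atol))
    rows = []
    for j, ct in enumerate(traj.cell_types):
        reps = design.replicates_for(ct)
        sig = noise.sigma_for(ct)
        ntot = traj.n_tot[:, j]
        for d, r, mu in zip(days, reps, ntot):
            eps = rng.normal(0.0, sig, size=r)
            for k in range(r):
                rows.append((d, str(ct), k + 1, mu * np.exp(eps[k])))
    return validate_counts(pd.DataFrame(rows, columns=["day", "cell_type", "replicate", "count"]))


def generate_baseline(params, irr: IrradiationModel, design: StudyDesign | None = None,
                      noise: NoiseModel | None = None, seed=None) -> pd.DataFrame:
    """Unperturbed samples at the steady state (the right-panel analogue).

    Sample sizes follow the design (default 15 thymocyte / 16 TEC animals);
    the noise model is the same as for the recovery time course.
    """
    from .models import steady_state

    design = design or StudyDesign()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    ss = steady_state(params, guess=irr.n_tot0)
    rows = []
    for j, ct in enumerate(irr.cell_types):
        name = str(ct)
        nrep = (design.baseline_n_thymocytes if name in _THYMOCYTES
                else design.baseline_n_tecs)
        sig = noise.sigma_for(ct)
        eps = rng.normal(0.0, sig, size=nrep)
        for k in range(nrep):
            rows.append((0.0, name, k + 1, ss.x[j] * np.exp(eps[k])))
    return validate_counts(pd.DataFrame(rows, columns=["day", "cell_type", "replicate", "count"]))


def _scale_dn(df: pd.DataFrame, factor: float) -> pd.DataFrame:
    out = validate_counts(df)
    mask = out["cell_type"] == "DN"
    out.loc[mask, "count"] = out.loc[mask, "count"] * factor
    return out


def apply_dn_contamination_correction(df: pd.DataFrame,
                                      fraction: float = DN_CONTAMINATION_PERCENT) -> pd.DataFrame:
    """Subtract the non-T-lineage fraction (percent) from the DN counts.

    The DN flow-cytometry gate contains a constant admixture of non-T cells
    (dendritic cells and others); modeling uses DN counts scaled by
    ``1 - fraction/100``.  Other cell types are untouched.
    """
    if not (0 <= fraction < 100):
        raise ValueError(f"contamination fraction must be in [0, 100), got {fraction}")
    return _scale_dn(df, 1.0 - fraction / 100.0)


def inflate_dn_contamination(df: pd.DataFrame,
                             fraction: float = DN_CONTAMINATION_PERCENT) -> pd.DataFrame:
    """Inverse of the correction: re-inflate DN counts by the same factor.

    Used to emulate raw (uncorrected) gate counts so the correction can be
    exercised round-trip.
    """
    if not (0 <= fraction < 100):
        raise ValueError(f"contamination fraction must be in [0, 100), got {fraction}")
    return _scale_dn(df, 1.0 / (1.0 - fraction / 100.0))


def estimate_dn_subpop_counts(total_dn: pd.Series, proportions: pd.DataFrame,
                              tol: float = 1e-6) -> pd.DataFrame:
    """Split per-day total DN counts into DN1-DN4 using stage proportions.

    ``total_dn`` is indexed by day; ``proportions`` has one row per day with
    columns DN1..DN4 summing to one.  Days present in ``total_dn`` but
    missing from ``proportions`` get the mean of the two neighbouring
    observed days' proportions (the rule used for the unsampled days 12 and
    14); a missing day without an observed neighbour on each side is
    rejected.
    """
    cols = ["DN1", "DN2", "DN3", "DN4"]
    props = proportions.loc[:, cols].astype(float)
    sums = props.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=tol):
        bad = props.index[~np.isclose(sums, 1.0, atol=tol)].tolist()
        raise ValueError(f"stage proportions must sum to 1; offending day(s): {bad}")
    obs_days = np.asarray(sorted(props.index), dtype=float)
    out = {}
    for day, total in total_dn.sort_index().items():
        d = float(day)
        if d in props.index:
            p = props.loc[d].to_numpy()
        else:
            before = obs_days[obs_days < d]
            after = obs_days[obs_days > d]
            if len(before) == 0 or len(after) == 0:
                raise ValueError(
                    f"day {d} has no observed stage proportions and lacks a "
                    "neighbour on each side")
            p = 0.5 * (props.loc[before[-1]].to_numpy() + props.loc[after[0]].to_numpy())
            p = p / p.sum()
        out[d] = total * p
    return pd.DataFrame.from_dict(out, orient="index", columns=cols).rename_axis("day")
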