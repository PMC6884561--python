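"""Cell types, kinetic parameter sets, and the irradiation observation model.

The package models five thymic compartments — DN, DP and SP4 thymocytes plus
cortical and medullary thymic epithelial cells (cTEC, mTEC) — and, in the
detailed topology, the four DN sub-stages DN1–DN4.  All parameter containers
are plain dataclasses with a fixed field order that matches the flat array
layout consumed by the compiled right-hand-side kernels.

Units are fixed package-wide: time in days, populations in absolute cell
counts.  Influxes are cells·day⁻¹, per-capita rates day⁻¹, interaction
coefficients day⁻¹·cell⁻¹, carrying capacities cells, delays days.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "CellType",
    "COARSE_TYPES",
    "DETAILED_TYPES",
    "Topology",
    "AltVariant",
    "CoarseParams",
    "DetailedParams",
    "AlternativeParams",
    "IrradiationModel",
    "FRACTION_PARAMS",
    "params_to_yaml",
    "params_from_yaml",
]


class CellType(str, enum.Enum):
    """Compartment labels; the coarse state vector order is DN, DP, cTEC, SP4, mTEC."""

    DN = "DN"
    DP = "DP"
    CTEC = "cTEC"
    SP4 = "SP4"
    MTEC = "mTEC"
    DN1 = "DN1"
    DN2 = "DN2"
    DN3 = "DN3"
    DN4 = "DN4"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: State-vector orders.  The coarse order mirrors the equation order of the
#: model (DN, DP, cTEC, SP4, mTEC); the detailed model tracks DN1–DN4, DP, cTEC.
COARSE_TYPES = (CellType.DN, CellType.DP, CellType.CTEC, CellType.SP4, CellType.MTEC)
DETAILED_TYPES = (
    CellType.DN1,
    CellType.DN2,
    CellType.DN3,
    CellType.DN4,
    CellType.DP,
    CellType.CTEC,
)


class Topology(enum.IntEnum):
    """Model topology identifiers understood by the compiled kernels."""

    COARSE = 0
    DETAILED = 1
    M1_NO_MTEC_SELFSUPPRESSION = 2
    M2_DN_TO_MTEC = 3
    M3_CTEC_BOOSTS_DP = 4
    M4_DP_TO_CTEC = 5
    #: detailed model with the printed "+" sign on the DN2–DN4 cTEC-dependent
    #: term (flux *into* the stage instead of out of it); kept for comparison
    #: with the flux-conserving default.
    DETAILED_VERBATIM = 6


#: Alternative-topology variants (aliases into :class:`Topology`).
AltVariant = Topology


def _nonneg(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"parameter {name} is not finite: {value!r}")
    if value < 0:
        raise ValueError(f"parameter {name} must be >= 0, got {value!r}")


def _fraction(name: str, value: float) -> None:
    _nonneg(name, value)
    if value > 1:
        raise ValueError(f"parameter {name} is a fraction and must be <= 1, got {value!r}")


#: Parameters that are fractions (searched on [0, 1] during estimation).
FRACTION_PARAMS = frozenset(
    {"r1", "r24", "rDN4"}
    | {f"p_{t.value}" for t in CellType}
)


@dataclass
class CoarseParams:
    """Kinetic parameters of the five-compartment crosstalk model.

    The model couples DN, DP, SP4 thymocytes with cTECs and mTECs:

    * DN cells enter at rate ``phi1`` and are removed by cTECs (``mu1``), a
      fraction ``r1`` of the removed cells differentiating into DP.
    * DP cells proliferate logistically (``theta2``, ``K2``) and are removed
      by cTECs after a delay ``tau2`` (positive selection); a fraction
      ``r24`` of that outflux becomes SP4.
    * SP4 cells are exported/killed in proportion to mTECs (``mu4``).
    * cTECs grow in proportion to DN numbers (``muc``).
    * mTECs receive an SP4-dependent influx (``phim4``), grow logistically
      (``rm``, ``Km``) and are suppressed by DP cells after a delay ``taum``.
    """

    phi1: float = 0.0      # DN influx, cells/day
    delta1: float = 0.0    # DN net self-rate, 1/day
    mu1: float = 0.0       # cTEC-dependent DN removal, 1/(day*cell)
    r1: float = 0.0        # DN->DP transfer fraction, [0,1]
    theta2: float = 0.0    # DP logistic proliferation rate, 1/day
    K2: float = 1.0        # DP carrying capacity, cells
    mu2: float = 0.0       # cTEC-dependent DP removal, 1/(day*cell)
    tau2: float = 0.0      # delay of cTEC action on DP, days
    r24: float = 0.0       # fraction of DP outflux reaching SP4, [0,1]
    mu4: float = 0.0       # mTEC-dependent SP4 removal, 1/(day*cell)
    phic: float = 0.0      # cTEC influx, cells/day
    deltac: float = 0.0    # cTEC death rate, 1/day
    muc: float = 0.0       # DN-dependent cTEC growth, 1/(day*cell)
    phim: float = 0.0      # mTEC influx, cells/day
    phim4: float = 0.0     # SP4-dependent mTEC influx coefficient, 1/day
    rm: float = 0.0        # mTEC logistic rate, 1/day
    Km: float = 1.0        # mTEC carrying capacity, cells
    gammamp: float = 0.0   # DP-dependent mTEC suppression, 1/(day*cell)
    taum: float = 0.0      # delay of DP action on mTEC, days

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            setattr(self, f.name, v)
            if f.name in FRACTION_PARAMS:
                _fraction(f.name, v)
            else:
                _nonneg(f.name, v)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=np.float64)

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CoarseParams":
        return cls(**dict(zip(cls.names(), np.asarray(arr, dtype=float))))

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **overrides: float) -> "CoarseParams":
        d = self.to_dict()
        unknown = set(overrides) - set(d)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        d.update(overrides)
        return CoarseParams(**d)


@dataclass
class DetailedParams:
    """Parameters of the DN1–DN4 / DP / cTEC detailed model.

    Each DN stage has a net self-rate ``deltaDN_i`` and a cTEC-dependent
    transition coefficient ``muDN_i`` moving cells to the next stage (the
    DN4 outflux feeds DP with transfer fraction ``rDN4``).  The cTEC
    equation sums per-stage growth contributions ``muCTEC_j``.  DP and cTEC
    parameters are shared with the coarse model and are normally fixed to
    the coarse estimates during two-stage estimation.
    """

    phi1: float = 0.0
    deltaDN1: float = 0.0
    deltaDN2: float = 0.0
    deltaDN3: float = 0.0
    deltaDN4: float = 0.0
    muDN1: float = 0.0
    muDN2: float = 0.0
    muDN3: float = 0.0
    muDN4: float = 0.0
    rDN4: float = 0.0
    muCTEC1: float = 0.0
    muCTEC2: float = 0.0
    muCTEC3: float = 0.0
    muCTEC4: float = 0.0
    theta2: float = 0.0
    K2: float = 1.0
    mu2: float = 0.0
    tau2: float = 0.0
    phic: float = 0.0
    deltac: float = 0.0

    __post_init__ = CoarseParams.__post_init__
    to_array = CoarseParams.to_array
    to_dict = CoarseParams.to_dict

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "DetailedParams":
        return cls(**dict(zip(cls.names(), np.asarray(arr, dtype=float))))

    def replace(self, **overrides: float) -> "DetailedParams":
        d = self.to_dict()
        unknown = set(overrides) - set(d)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        d.update(overrides)
        return DetailedParams(**d)


#: extra parameters used by the alternative topologies, in kernel order
EXTRA_NAMES = ("mum", "phimn", "r2", "gammac")


@dataclass
class AlternativeParams:
    """Coarse parameters plus the variant-specific extras of topologies M1–M4.

    ``variant`` selects which single equation of the coarse model is
    replaced: M1 drops the mTEC logistic term in favour of a death rate
    ``mum``; M2 replaces the mTEC equation by DN-driven influx ``phimn``
    plus death ``mum``; M3 lets cTECs *promote* DP growth (logistic rate
    ``r2``, and the ``mu2`` term enters with a plus sign, undelayed, exactly
    as printed); M4 adds a delayed DP-dependent suppression ``gammac`` to
    the cTEC equation.
    """

    variant: Topology = Topology.M4_DP_TO_CTEC
    base: CoarseParams = field(default_factory=CoarseParams)
    mum: float = 0.0     # mTEC death rate (M1, M2), 1/day
    phimn: float = 0.0   # DN-dependent mTEC influx (M2), 1/day
    r2: float = 0.0      # DP logistic rate (M3), 1/day
    gammac: float = 0.0  # DP-dependent cTEC suppression (M4), 1/(day*cell)

    def __post_init__(self) -> None:
        self.variant = Topology(self.variant)
        if self.variant not in (
            Topology.M1_NO_MTEC_SELFSUPPRESSION,
            Topology.M2_DN_TO_MTEC,
            Topology.M3_CTEC_BOOSTS_DP,
            Topology.M4_DP_TO_CTEC,
        ):
            raise ValueError(f"not an alternative-topology variant: {self.variant!r}")
        for name in EXTRA_NAMES:
            _nonneg(name, float(getattr(self, name)))

    def extras_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in EXTRA_NAMES], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        d = self.base.to_dict()
        for n in EXTRA_NAMES:
            d[n] = float(getattr(self, n))
        return d

    def replace(self, **overrides: float) -> "AlternativeParams":
        extras = {n: float(getattr(self, n)) for n in EXTRA_NAMES}
        base_over = {}
        for k, v in overrides.items():
            if k in extras:
                extras[k] = v
            else:
                base_over[k] = v
        return AlternativeParams(
            variant=self.variant, base=self.base.replace(**base_over), **extras
        )


@dataclass
class IrradiationModel:
    """Biphasic observation layer splitting counts into dying and surviving pools.

    For each compartment the pre-irradiation size ``n_tot0`` is split at t=0
    into a surviving fraction ``p`` (which seeds the dynamic model) and a
    dying pool ``(1-p)*n_tot0`` that decays exponentially at rate ``omega``.
    The observable is n_tot(t) = n_x(t) + n(t); before irradiation (t<0) the
    dynamic history is held at ``n_tot0`` and n_x is zero.
    """

    cell_types: tuple[CellType, ...]
    n_tot0: np.ndarray  # pre-irradiation sizes, cells
    p: np.ndarray       # survival fractions, [0,1]
    omega: np.ndarray   # decay rates of the dying pool, 1/day

    def __post_init__(self) -> None:
        self.cell_types = tuple(CellType(t) for t in self.cell_types)
        k = len(self.cell_types)
        self.n_tot0 = np.asarray(self.n_tot0, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        self.omega = np.asarray(self.omega, dtype=np.float64)
        for name, arr in (("n_tot0", self.n_tot0), ("p", self.p), ("omega", self.omega)):
            if arr.shape != (k,):
                raise ValueError(f"{name} must have shape ({k},), got {arr.shape}")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if np.any(self.p > 1):
            raise ValueError("survival fractions p must lie in [0, 1]")

    @classmethod
    def from_dicts(
        cls,
        cell_types: tuple[CellType, ...],
        n_tot0: Mapping[CellType | str, float],
        p: Mapping[CellType | str, float],
        omega: Mapping[CellType | str, float],
    ) -> "IrradiationModel":
        cts = tuple(CellType(t) for t in cell_types)

        def vec(m: Mapping) -> np.ndarray:
            mm = {CellType(k): v for k, v in m.items()}
            return np.array([mm[t] for t in cts], dtype=np.float64)

        return cls(cts, vec(n_tot0), vec(p), vec(omega))

    def index(self, cell_type: CellType | str) -> int:
        return self.cell_types.index(CellType(cell_type))

    def survivors0(self) -> np.ndarray:
        """Initial condition of the dynamic model: n(0) = p * n_tot0."""
        return self.p * self.n_tot0

    def decayed(self, t, cell_type: CellType | str):
        """Dying-pool size n_x(t) = n_tot0*(1-p)*exp(-omega*t); zero for t < 0."""
        i = self.index(cell_type)
        t = np.asarray(t, dtype=float)
        out = self.n_tot0[i] * (1.0 - self.p[i]) * np.exp(-self.omega[i] * np.minimum(t, 700 / max(self.omega[i], 1e-300)))
        out = np.where(t < 0, 0.0, out)
        return out if out.ndim else float(out)

    def decayed_matrix(self, t: np.ndarray) -> np.ndarray:
        """n_x for all compartments on a time grid; shape (len(t), k)."""
        t = np.asarray(t, dtype=float)[:, None]
        out = self.n_tot0 * (1.0 - self.p) * np.exp(-self.omega * t)
        return np.where(t < 0, 0.0, out)

    def to_dict(self) -> dict[str, float]:
        d: dict[str, float] = {}
        for j, ct in enumerate(self.cell_types):
            d[f"ntot0_{ct.value}"] = float(self.n_tot0[j])
            d[f"p_{ct.value}"] = float(self.p[j])
            d[f"omega_{ct.value}"] = float(self.omega[j])
        return d

    @classmethod
    def from_flat_dict(cls, cell_types, d: Mapping[str, float]) -> "IrradiationModel":
        cts = tuple(CellType(t) for t in cell_types)
        return cls(
            cts,
            np.array([d[f"ntot0_{t.value}"] for t in cts]),
            np.array([d[f"p_{t.value}"] for t in cts]),
            np.array([d[f"omega_{t.value}"] for t in cts]),
        )


def decayed_count(t: float, irr: IrradiationModel, cell_type: CellType | str) -> float:
    """Irradiation-killed pool of one compartment at time t (cells)."""
    return irr.decayed(t, cell_type)


# --- plain-text (YAML) serialization of flat parameter documents -----------

def params_to_yaml(d: Mapping[str, float], path) -> None:
    """Write a flat key->value parameter document (human-readable YAML)."""
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in d.items()}, fh, sort_keys=True)


def params_from_yaml(path) -> dict[str, float]:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path} does not contain a flat parameter mapping")
    return {str(k): float(v) for k, v in d.items()}
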