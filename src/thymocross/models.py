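"""Model right-hand sides and steady-state computation.

These wrappers expose the compiled kernels for single evaluations (mainly
for inspection and testing) and provide the damped-Newton steady-state
solver used by the derived-kinetics and experiment layers.  Delays are
irrelevant at equilibrium, so the steady state is a root of the undelayed
right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dde
from .params import (
    AlternativeParams,
    CoarseParams,
    DetailedParams,
    Topology,
    decayed_count,  # re-exported: observation-layer primitive  # noqa: F401
)

__all__ = [
    "rhs_coarse",
    "rhs_detailed",
    "rhs_alternative",
    "undelayed_rhs",
    "jacobian",
    "SteadyStateResult",
    "steady_state",
    "decayed_count",
]

_ZERO_EX = np.zeros(4)


def _check_finite(name: str, arr) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        bad = np.flatnonzero(~np.isfinite(np.atleast_1d(arr)))
        raise ValueError(f"non-finite value in {name} at component(s) {bad.tolist()}")
    return arr


def rhs_coarse(t: float, state, lagged_ctec: float, lagged_dp: float,
               params: CoarseParams) -> np.ndarray:
    """Derivative of the coarse model state [DN, DP, cTEC, SP4, mTEC].

    ``lagged_ctec`` is n_cTEC(t - tau2), ``lagged_dp`` is n_DP(t - taum).
    """
    state = _check_finite("state", state)
    if state.shape != (5,):
        raise ValueError(f"coarse state must be a 5-vector, got shape {state.shape}")
    _check_finite("lagged cTEC", lagged_ctec)
    _check_finite("lagged DP", lagged_dp)
    return _dde._rhs_once(_dde.COARSE, t, state, float(lagged_ctec),
                          float(lagged_dp), params.to_array(), _ZERO_EX)


def rhs_detailed(t: float, state, lagged_ctec: float, params: DetailedParams,
                 verbatim: bool = False) -> np.ndarray:
    """Derivative of the detailed model state [DN1..DN4, DP, cTEC].

    By default the cTEC-dependent term of DN2-DN4 is an outflux (minus sign),
    conserving flux between consecutive stages; ``verbatim=True`` reproduces
    the plus sign as printed.
    """
    state = _check_finite("state", state)
    if state.shape != (6,):
        raise ValueError(f"detailed state must be a 6-vector, got shape {state.shape}")
    _check_finite("lagged cTEC", lagged_ctec)
    topo = _dde.DETAILED_VERBATIM if verbatim else _dde.DETAILED
    return _dde._rhs_once(topo, t, state, float(lagged_ctec), 0.0,
                          params.to_array(), _ZERO_EX)


def rhs_alternative(t: float, state, lagged_ctec: float, lagged_dp: float,
                    params: AlternativeParams) -> np.ndarray:
    """Derivative under an alternative topology (M1-M4).

    Only the variant's replaced equation differs from the coarse model;
    lagged values a variant does not use are ignored.
    """
    state = _check_finite("state", state)
    if state.shape != (5,):
        raise ValueError(f"state must be a 5-vector, got shape {state.shape}")
    _check_finite("lagged cTEC", lagged_ctec)
    _check_finite("lagged DP", lagged_dp)
    return _dde._rhs_once(int(params.variant), t, state, float(lagged_ctec),
                          float(lagged_dp), params.base.to_array(),
                          params.extras_array())


def _split(params):
    """(topology id, coarse-or-detailed array, extras array) for any parameter set."""
    if isinstance(params, AlternativeParams):
        return int(params.variant), params.base.to_array(), params.extras_array()
    if isinstance(params, DetailedParams):
        return _dde.DETAILED, params.to_array(), _ZERO_EX
    if isinstance(params, CoarseParams):
        return _dde.COARSE, params.to_array(), _ZERO_EX
    raise TypeError(f"unsupported parameter set type: {type(params)!r}")


def undelayed_rhs(params, state: np.ndarray) -> np.ndarray:
    """Right-hand side with every lagged value replaced by the current state."""
    topo, p, ex = _split(params)
    state = np.asarray(state, dtype=np.float64)
    if topo in (_dde.DETAILED, _dde.DETAILED_VERBATIM):
        lagc, lagdp = state[5], 0.0
    else:
        lagc, lagdp = state[2], state[1]
    return _dde._rhs_once(topo, 0.0, state, lagc, lagdp, p, ex)


def jacobian(params, state: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the undelayed right-hand side."""
    x = np.asarray(state, dtype=np.float64)
    if isinstance(params, DetailedParams):
        q = params
        D = x[:4]
        P, c = x[4], x[5]
        dlt = [q.deltaDN1, q.deltaDN2, q.deltaDN3, q.deltaDN4]
        mu = [q.muDN1, q.muDN2, q.muDN3, q.muDN4]
        mc = [q.muCTEC1, q.muCTEC2, q.muCTEC3, q.muCTEC4]
        J = np.zeros((6, 6))
        J[0, 0] = dlt[0] - mu[0] * c
        J[0, 5] = -mu[0] * D[0]
        for k in range(1, 4):
            J[k, k - 1] = mu[k - 1] * c
            J[k, k] = dlt[k] - mu[k] * c
            J[k, 5] = mu[k - 1] * D[k - 1] - mu[k] * D[k]
        J[4, 3] = q.rDN4 * mu[3] * c
        J[4, 4] = q.theta2 * (1.0 - 2.0 * P / q.K2) - q.mu2 * c
        J[4, 5] = q.rDN4 * mu[3] * D[3] - q.mu2 * P
        for j in range(4):
            J[5, j] = mc[j] * c
        J[5, 5] = -q.deltac + sum(mc[j] * D[j] for j in range(4))
        return J

    if isinstance(params, AlternativeParams):
        base, variant = params.base, params.variant
    else:
        base, variant = params, Topology.COARSE
    b = base
    D, P, c, S, m = x
    J = np.zeros((5, 5))
    J[0, 0] = b.delta1 - b.mu1 * c
    J[0, 2] = -b.mu1 * D
    if variant == Topology.M3_CTEC_BOOSTS_DP:
        J[1, 0] = b.mu1 * b.r1 * c
        J[1, 1] = params.r2 * (1.0 - 2.0 * P / b.K2) + b.mu2 * c
        J[1, 2] = b.mu1 * b.r1 * D + b.mu2 * P
    else:
        J[1, 0] = b.mu1 * b.r1 * c
        J[1, 1] = b.theta2 * (1.0 - 2.0 * P / b.K2) - b.mu2 * c
        J[1, 2] = b.mu1 * b.r1 * D - b.mu2 * P
    if variant == Topology.M4_DP_TO_CTEC:
        J[2, 0] = b.muc * c
        J[2, 1] = -params.gammac * c
        J[2, 2] = -b.deltac + b.muc * D - params.gammac * P
    else:
        J[2, 0] = b.muc * c
        J[2, 2] = -b.deltac + b.muc * D
    J[3, 1] = b.mu2 * b.r24 * c
    J[3, 2] = b.mu2 * b.r24 * P
    J[3, 3] = -b.mu4 * m
    J[3, 4] = -b.mu4 * S
    if variant == Topology.M1_NO_MTEC_SELFSUPPRESSION:
        J[4, 1] = -b.gammamp * m
        J[4, 3] = b.phim4
        J[4, 4] = -(b.gammamp * P + params.mum)
    elif variant == Topology.M2_DN_TO_MTEC:
        J[4, 0] = params.phimn
        J[4, 3] = b.phim4
        J[4, 4] = -params.mum
    else:
        J[4, 1] = -b.gammamp * m
        J[4, 3] = b.phim4
        J[4, 4] = b.rm * (1.0 - 2.0 * m / b.Km) - b.gammamp * P
    return J


@dataclass
class SteadyStateResult:
    """Root of the undelayed right-hand side reached from a given guess."""

    x: np.ndarray
    residual: np.ndarray
    residual_norm: float
    converged: bool
    iterations: int

    def __iter__(self):  # allow tuple-style unpacking of the state
        return iter(self.x)


def steady_state(params, guess=None, *, irr=None, tol: float = 1e-9,
                 max_iter: int = 200) -> SteadyStateResult:
    """Damped-Newton steady state of a model topology.

    The root depends on the starting point when multiple equilibria exist;
    the one reached from ``guess`` is returned.  If ``guess`` is omitted an
    irradiation model must be supplied and the final point of a long forward
    simulation (t = 400 days) is used, which lands on the attractor of the
    post-irradiation dynamics.

    Convergence criterion: max_i |f_i| / max(x_i, 1) < ``tol`` (a per-capita
    residual rate in day^-1).
    """
    if guess is None:
        if irr is None:
            raise ValueError("provide a strictly positive guess or an irradiation model")
        from .simulate import SimulationSpec, simulate

        spec = SimulationSpec(params=params, irr=irr,
                              grid=np.array([0.0, 400.0]))
        guess = simulate(spec).n[-1]
    x = np.asarray(guess, dtype=np.float64).copy()
    if np.any(x <= 0):
        raise ValueError("steady-state guess must be strictly positive")

    def scaled_norm(f, scale):
        return float(np.max(np.abs(f) / scale))

    f = undelayed_rhs(params, x)
    it = 0
    for it in range(1, max_iter + 1):
        scale = np.maximum(np.abs(x), 1.0)
        best = scaled_norm(f, scale)
        if best < tol:
            break
        J = jacobian(params, x)
        try:
            dx = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -f, rcond=None)[0]
        lam = 1.0
        improved = False
        for _ in range(60):
            x_new = x + lam * dx
            if np.all(np.isfinite(x_new)) and np.all(x_new > 0):
                f_new = undelayed_rhs(params, x_new)
                # scale held fixed during the line search so the Newton
                # direction remains a descent direction for the merit norm
                if scaled_norm(f_new, scale) < best:
                    x, f = x_new, f_new
                    improved = True
                    break
            lam *= 0.5
        if not improved:
            break
    best = scaled_norm(f, np.maximum(np.abs(x), 1.0))
    return SteadyStateResult(
        x=x,
        residual=f,
        residual_norm=best,
        converged=bool(best < tol),
        iterations=it,
    )
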