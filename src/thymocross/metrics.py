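"""Composite kinetic quantities evaluated at the steady state.

These are the literature-comparable numbers: influx, apparent (net)
proliferation, differentiation and export rates, residence times in hours,
and the DP-to-SP4 export fraction.  Apparent rates are marginal rates —
population-size data cannot separate pure proliferation from apoptosis, so
no pure rate is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .models import steady_state
from .params import CoarseParams

__all__ = ["DerivedQuantities", "derive", "derive_from_fit", "bootstrap_derived"]

HOURS_PER_DAY = 24.0


@dataclass
class DerivedQuantities:
    """Composite kinetic quantities of the coarse model at a steady state."""

    dn_inflow: float                 # cells/day
    dn_apparent_proliferation: float  # 1/day
    dn_differentiation: float        # 1/day
    dn_residence_h: float            # hours
    dp_apparent_proliferation: float  # 1/day
    dp_differentiation_sp4: float    # 1/day
    dp_residence_h: float            # hours
    dp_to_sp4_fraction: float        # percent
    sp4_apparent_export: float       # 1/day

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        units = {
            "dn_inflow": "cells/day",
            "dn_apparent_proliferation": "1/day",
            "dn_differentiation": "1/day",
            "dn_residence_h": "h",
            "dp_apparent_proliferation": "1/day",
            "dp_differentiation_sp4": "1/day",
            "dp_residence_h": "h",
            "dp_to_sp4_fraction": "%",
            "sp4_apparent_export": "1/day",
        }
        d = self.to_dict()
        return pd.DataFrame(
            [(k, d[k], units[k]) for k in d], columns=["quantity", "value", "units"])


def derive(params: CoarseParams, nstar) -> DerivedQuantities:
    """Composite quantities from parameters and a (verified) steady state.

    ``nstar`` is the steady-state vector [DN, DP, cTEC, SP4, mTEC].  A zero
    differentiation rate yields an infinite residence time.
    """
    nstar = np.asarray(list(nstar), dtype=float)
    if nstar.shape != (5,):
        raise ValueError("nstar must be the 5-compartment steady state")
    dn, dp, ctec, sp4, mtec = nstar
    dn_diff = params.mu1 * params.r1 * ctec
    dp_diff = params.r24 * params.mu2 * ctec
    return DerivedQuantities(
        dn_inflow=params.phi1,
        dn_apparent_proliferation=params.delta1 - params.mu1 * (1.0 - params.r1) * ctec,
        dn_differentiation=dn_diff,
        dn_residence_h=HOURS_PER_DAY / dn_diff if dn_diff > 0 else np.inf,
        dp_apparent_proliferation=(
            params.theta2 * (1.0 - dp / params.K2) - (1.0 - params.r24) * params.mu2 * ctec),
        dp_differentiation_sp4=dp_diff,
        dp_residence_h=HOURS_PER_DAY / dp_diff if dp_diff > 0 else np.inf,
        dp_to_sp4_fraction=100.0 * params.r24,
        sp4_apparent_export=params.mu4 * mtec,
    )


def derive_from_fit(fit_result, guess=None) -> DerivedQuantities:
    """Steady state of the fitted model, then the composite quantities."""
    params = fit_result.params
    if not isinstance(params, CoarseParams):
        raise ValueError("derived quantities are defined for the coarse topology")
    if guess is None:
        guess = fit_result.irr.n_tot0
    ss = steady_state(params, guess)
    if not ss.converged:
        raise RuntimeError(
            f"steady state did not converge (residual {ss.residual_norm:.3g})")
    return derive(params, ss.x)


def bootstrap_derived(bootstrap_result, problem, alpha: float | None = None):
    """Derived-quantity samples and percentile intervals from a bootstrap run.

    Re-evaluates the composite quantities for every converged bootstrap
    parameter sample (steady state re-solved per sample) and returns
    ``(samples DataFrame, intervals dict)``.
    """
    from .estimation import values_to_params

    alpha = bootstrap_result.alpha if alpha is None else alpha
    names = None
    rows = []
    guess = np.array([problem.values[f"ntot0_{c}"] for c in problem._cts])
    for b in range(bootstrap_result.B):
        if not bootstrap_result.converged[b]:
            continue
        vals = dict(problem.values)
        for k, n in enumerate(bootstrap_result.parameters):
            vals[n] = bootstrap_result.samples[b, k]
        params = values_to_params(problem.topology, vals)
        ss = steady_state(params, guess)
        if not ss.converged:
            continue
        dq = derive(params, ss.x).to_dict()
        names = list(dq)
        rows.append({"resample_index": b, **dq})
    samples = pd.DataFrame(rows)
    lo_q, hi_q = 100.0 * (1 - alpha) / 2.0, 100.0 * (1 + alpha) / 2.0
    intervals = {}
    for n in names or []:
        v = samples[n].to_numpy()
        intervals[n] = (float(np.percentile(v, lo_q)), float(np.percentile(v, hi_q)))
    return samples, intervals
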