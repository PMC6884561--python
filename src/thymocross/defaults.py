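"""Default ("study-like") truth regime for synthetic-data studies.

These constants define the stated world of the synthetic generator.  They are
constructed, once, from documented steady-state targets so that the derived
composite kinetic quantities (inflow, apparent proliferation, differentiation
and export rates, residence times, DP-to-SP4 fraction) equal the published
point estimates of the recovery study, and the trajectories show the
characteristic post-irradiation shape: exponential decay for a few days,
recovery onset within ten days, and DP/mTEC overshoot with an interior peak.
They are documented modelling choices, not claims about the study's fitted
values.

Construction sketch (steady-state targets: DN* = 3.3e6, DP* = 1.5e8,
cTEC* = 1e4, mTEC* = 3e4):

* ``mu1*r1*cTEC* = 0.14``/day (DN differentiation) with a small transfer
  fraction r1 = 0.2, which leaves the DN pool nearly self-sustaining
  (delta1 close to mu1*cTEC*) and the DN influx phi1 weakly identified —
  the regime in which replacing phi1 by a much smaller value barely moves
  the trajectories.
* ``delta1 - mu1*(1-r1)*cTEC* = 0.13``/day (DN apparent proliferation).
* DP logistic rate theta2 = 1.7/day with K2 fixed by the DP steady state;
  ``r24*mu2*cTEC* = 0.11``/day and r24 = 0.10.
* ``mu4*mTEC* = 0.52``/day (SP4 apparent export).
* cTEC and mTEC influx/death parameters balance the remaining equations.
"""

from __future__ import annotations


from .params import CoarseParams, DetailedParams, IrradiationModel, COARSE_TYPES, DETAILED_TYPES

__all__ = [
    "STEADY_TARGETS",
    "default_coarse_truth",
    "default_irradiation",
    "default_detailed_truth",
    "default_detailed_irradiation",
]

#: steady-state population targets (cells)
STEADY_TARGETS = {
    "DN": 3.3e6,
    "DP": 1.5e8,
    "cTEC": 1.0e4,
    "SP4": 1.65e7 / 0.52,   # DP->SP4 flux / SP4 export rate
    "mTEC": 3.0e4,
}

# documented composite-rate targets (per day, except r24)
_DN_DIFF = 0.14          # mu1*r1*cTEC*
_DN_APPARENT = 0.13      # delta1 - mu1*(1-r1)*cTEC*
_DP_DIFF = 0.11          # r24*mu2*cTEC*
_SP4_EXPORT = 0.52       # mu4*mTEC*
_R24 = 0.10
_PHI1 = 3.3e4            # cells/day


def default_coarse_truth() -> CoarseParams:
    """The shipped coarse-model truth parameter set."""
    Dstar = STEADY_TARGETS["DN"]
    P = STEADY_TARGETS["DP"]
    c = STEADY_TARGETS["cTEC"]
    S = STEADY_TARGETS["SP4"]
    m = STEADY_TARGETS["mTEC"]

    r1 = 0.12
    mu1 = _DN_DIFF / (r1 * c)
    delta1 = _DN_APPARENT + mu1 * (1.0 - r1) * c

    mu2 = _DP_DIFF / (_R24 * c)
    # DP influx at steady state balances the logistic/removal bracket
    dp_influx = mu1 * r1 * c * Dstar
    theta2 = 1.7
    log_term = mu2 * c - dp_influx / P       # theta2*(1 - P/K2)
    K2 = P / (1.0 - log_term / theta2)

    mu4 = _SP4_EXPORT / m

    phic = 3000.0
    deltac = 0.5
    muc = (deltac - phic / c) / Dstar

    gammamp = 0.35 / P
    rm = 0.5
    phim = 30.0
    phim4 = 1459.6 / S
    # rm*(1 - m/Km) balances suppression + influx at the mTEC steady state
    bracket = gammamp * P - (phim + phim4 * S) / m
    Km = m / (1.0 - bracket / rm)

    return CoarseParams(
        phi1=_PHI1, delta1=delta1, mu1=mu1, r1=r1,
        theta2=theta2, K2=K2, mu2=mu2, tau2=2.0,
        r24=_R24, mu4=mu4,
        phic=phic, deltac=deltac, muc=muc,
        phim=phim, phim4=phim4, rm=rm, Km=Km,
        gammamp=gammamp, taum=3.0,
    )


def default_irradiation() -> IrradiationModel:
    """Survival fractions and dying-pool decay rates after 4.5 Gy, coarse model.

    Pre-irradiation sizes are the steady-state targets; survival fractions
    and decay rates are chosen to give the observed two-order-of-magnitude
    drop of the radio-sensitive thymocytes within ~4 days.
    """
    return IrradiationModel.from_dicts(
        COARSE_TYPES,
        n_tot0={t: STEADY_TARGETS[t.value] for t in COARSE_TYPES},
        p={"DN": 0.25, "DP": 0.005, "cTEC": 0.2, "SP4": 0.05, "mTEC": 0.15},
        omega={"DN": 1.0, "DP": 1.2, "cTEC": 0.8, "SP4": 1.0, "mTEC": 0.8},
    )

#: steady-state targets of the DN sub-stages (cells); DN3/DN4 dominate
DN_STAGE_TARGETS = {"DN1": 1.5e5, "DN2": 1.0e5, "DN3": 2.0e6, "DN4": 1.05e6}

#: per-stage cTEC-dependent transition rates at the steady state (1/day)
_STAGE_RATES = {"DN1": 0.3, "DN2": 0.6, "DN3": 0.43, "DN4": 1.0}


def default_detailed_truth(phi1: float = 66.0) -> DetailedParams:
    """Detailed-model truth consistent with the coarse defaults.

    The DN1 influx defaults to a value hundreds of times smaller than the
    coarse-model phi1 (the biologically plausible progenitor influx); the
    stage parameters are solved so the stage steady states hit
    ``DN_STAGE_TARGETS`` and the flux into DP matches the coarse model.
    """
    coarse = default_coarse_truth()
    c = STEADY_TARGETS["cTEC"]
    D = [DN_STAGE_TARGETS[f"DN{i}"] for i in range(1, 5)]
    rate = [_STAGE_RATES[f"DN{i}"] for i in range(1, 5)]
    mu = [r / c for r in rate]

    delta = [rate[0] - phi1 / D[0]]
    for i in range(1, 4):
        influx = rate[i - 1] * D[i - 1]
        delta.append(rate[i] - influx / D[i])

    dp_influx = coarse.mu1 * coarse.r1 * c * STEADY_TARGETS["DN"]
    rDN4 = dp_influx / (rate[3] * D[3])
    # same per-DN-cell cTEC growth as the coarse model
    muCTEC = coarse.muc

    return DetailedParams(
        phi1=phi1,
        deltaDN1=delta[0], deltaDN2=delta[1], deltaDN3=delta[2], deltaDN4=delta[3],
        muDN1=mu[0], muDN2=mu[1], muDN3=mu[2], muDN4=mu[3],
        rDN4=rDN4,
        muCTEC1=muCTEC, muCTEC2=muCTEC, muCTEC3=muCTEC, muCTEC4=muCTEC,
        theta2=coarse.theta2, K2=coarse.K2, mu2=coarse.mu2, tau2=coarse.tau2,
        phic=coarse.phic, deltac=coarse.deltac,
    )


def default_detailed_irradiation() -> IrradiationModel:
    """Irradiation model for the detailed state vector (DN1-4, DP, cTEC)."""
    n0 = {f"DN{i}": DN_STAGE_TARGETS[f"DN{i}"] for i in range(1, 5)}
    n0["DP"] = STEADY_TARGETS["DP"]
    n0["cTEC"] = STEADY_TARGETS["cTEC"]
    p = {f"DN{i}": 0.25 for i in range(1, 5)}
    p.update({"DP": 0.005, "cTEC": 0.2})
    om = {f"DN{i}": 1.0 for i in range(1, 5)}
    om.update({"DP": 1.2, "cTEC": 0.8})
    return IrradiationModel.from_dicts(DETAILED_TYPES, n_tot0=n0, p=p, omega=om)
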