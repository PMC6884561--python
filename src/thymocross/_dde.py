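"""Compiled right-hand sides and the delay-differential-equation stepper.

The integrator is an explicit Dormand-Prince RK45 with the quartic dense
output used for method-of-steps lag evaluation.  The Butcher tableau and
dense-output coefficients are taken verbatim from ``scipy.integrate.RK45``
(scipy has no DDE solver, but its tableau is the reference transcription).

Method of steps: the state history for t < 0 is the constant pre-irradiation
vector; the step size is capped at the smallest positive delay so every lag
query falls into already-completed steps (or the constant history), and steps
are forced to land on delay-induced derivative discontinuities
k1*tau2 + k2*taum up to a configured propagation order.  The rhs is
re-evaluated at every step start (no FSAL reuse) because the lagged *value*
jumps when a lag crosses the t = 0 state jump.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.integrate import RK45 as _RK45

# exact Dormand-Prince coefficients, transcribed from scipy
_A = np.ascontiguousarray(_RK45.A, dtype=np.float64)    # (6, 5)
_B = np.ascontiguousarray(_RK45.B, dtype=np.float64)    # (6,)
_C = np.ascontiguousarray(_RK45.C, dtype=np.float64)    # (6,)
_E = np.ascontiguousarray(_RK45.E, dtype=np.float64)    # (7,)
_P = np.ascontiguousarray(_RK45.P, dtype=np.float64)    # (7, 4)

# topology ids (mirrors params.Topology)
COARSE = 0
DETAILED = 1
M1 = 2
M2 = 3
M3 = 4
M4 = 5
DETAILED_VERBATIM = 6

# integration status codes
OK = 0
STEP_UNDERFLOW = 1
MAX_STEPS_EXCEEDED = 2
NONFINITE_STATE = 3


@njit(cache=True, inline="always")
def _rhs(topo, t, y, lagc, lagdp, p, ex, out):
    """Model right-hand side.

    ``lagc`` is cTEC evaluated at t - tau2, ``lagdp`` is DP at t - taum.
    ``p`` is the flat parameter array (coarse or detailed layout), ``ex`` the
    alternative-topology extras [mum, phimn, r2, gammac].
    """
    if topo == DETAILED or topo == DETAILED_VERBATIM:
        # layout: 0 phi1 | 1-4 deltaDN1..4 | 5-8 muDN1..4 | 9 rDN4
        #         10-13 muCTEC1..4 | 14 theta2 | 15 K2 | 16 mu2 | 17 tau2
        #         18 phic | 19 deltac;  state: DN1..DN4, DP, cTEC
        sign = 1.0 if topo == DETAILED_VERBATIM else -1.0
        c = y[5]
        out[0] = p[0] + (p[1] - p[5] * c) * y[0]
        for k in range(1, 4):
            out[k] = p[4 + k] * c * y[k - 1] + (p[1 + k] + sign * p[5 + k] * c) * y[k]
        out[4] = (
            p[9] * p[8] * c * y[3]
            + (p[14] * (1.0 - y[4] / p[15]) - p[16] * lagc) * y[4]
        )
        s = 0.0
        for j in range(4):
            s += p[10 + j] * y[j]
        out[5] = p[18] + (-p[19] + s) * c
        return

    # coarse layout: 0 phi1 | 1 delta1 | 2 mu1 | 3 r1 | 4 theta2 | 5 K2
    #   6 mu2 | 7 tau2 | 8 r24 | 9 mu4 | 10 phic | 11 deltac | 12 muc
    #   13 phim | 14 phim4 | 15 rm | 16 Km | 17 gammamp | 18 taum
    # state: DN, DP, cTEC, SP4, mTEC
    dn = y[0]
    dp = y[1]
    c = y[2]
    sp = y[3]
    m = y[4]

    out[0] = p[0] + (p[1] - p[2] * c) * dn

    if topo == M3:
        # cTECs promote DP increase; undelayed cTEC, plus sign, as printed
        out[1] = p[2] * p[3] * c * dn + ex[2] * dp * (1.0 - dp / p[5]) + p[6] * c * dp
    else:
        out[1] = p[2] * p[3] * c * dn + (p[4] * (1.0 - dp / p[5]) - p[6] * lagc) * dp

    if topo == M4:
        out[2] = p[10] + (-p[11] + p[12] * dn - ex[3] * lagdp) * c
    else:
        out[2] = p[10] + (-p[11] + p[12] * dn) * c

    out[3] = p[6] * p[8] * lagc * dp - p[9] * m * sp

    if topo == M1:
        out[4] = p[13] + p[14] * sp - (p[17] * lagdp + ex[0]) * m
    elif topo == M2:
        out[4] = ex[1] * dn + p[14] * sp - ex[0] * m
    else:
        out[4] = p[13] + p[14] * sp + (p[15] * (1.0 - m / p[16]) - p[17] * lagdp) * m


@njit(cache=True, inline="always")
def _sol_comp(s, comp, hist, ts0, hs, ys, Qs, nst):
    """Evaluate component ``comp`` of the solution at time ``s``.

    Constant history for s < 0; the post-jump initial value at s = 0; dense
    quartic interpolation inside completed steps otherwise.
    """
    if s < 0.0:
        return hist[comp]
    if nst == 0 or s <= ts0[0]:
        return ys[0, comp]
    i = np.searchsorted(ts0[:nst], s, side="right") - 1
    if i > nst - 1:
        i = nst - 1
    th = (s - ts0[i]) / hs[i]
    q = Qs[i, comp]
    return ys[i, comp] + hs[i] * th * (q[0] + th * (q[1] + th * (q[2] + th * q[3])))


@njit(cache=True, inline="always")
def _stage_rhs(topo, t_st, y_st, p, ex, delays, lag_idx, hist, ts0, hs, ys, Qs, nst, out):
    if delays[0] > 0.0:
        lagc = _sol_comp(t_st - delays[0], lag_idx[0], hist, ts0, hs, ys, Qs, nst)
    else:
        lagc = y_st[lag_idx[0]]
    if delays[1] > 0.0:
        lagdp = _sol_comp(t_st - delays[1], lag_idx[1], hist, ts0, hs, ys, Qs, nst)
    else:
        lagdp = y_st[lag_idx[1]]
    _rhs(topo, t_st, y_st, lagc, lagdp, p, ex, out)


@njit(cache=True)
def _integrate(topo, p, ex, y0, hist, delays, lag_idx, t_end, t_eval,
               rtol, atol, max_step, breaks, max_steps):
    """Integrate the DDE from 0 to ``t_end`` and evaluate at ``t_eval``.

    Returns (y_eval, status); on non-OK status y_eval is partially undefined
    and callers must treat the run as failed.
    """
    n = y0.shape[0]
    neval = t_eval.shape[0]
    y_eval = np.empty((neval, n))
    ts0 = np.empty(max_steps)
    hs = np.empty(max_steps)
    ys = np.empty((max_steps + 1, n))
    Qs = np.empty((max_steps, n, 4))
    K = np.empty((7, n))
    y_st = np.empty(n)
    ys[0] = y0

    # step cap: smallest positive delay keeps lag queries out of the current step
    hcap = max_step
    for l in range(delays.shape[0]):
        if 0.0 < delays[l] < hcap:
            hcap = delays[l]

    status = OK
    nst = 0
    t = 0.0
    y = y0.copy()
    nb = breaks.shape[0]
    ib = 0
    h = min(hcap, 1e-2)
    err_exp = -0.2  # 1/(order+1) for the 4th-order error estimator

    while t < t_end - 1e-12 * max(1.0, t_end):
        if nst >= max_steps:
            status = MAX_STEPS_EXCEEDED
            break
        while ib < nb and breaks[ib] <= t + 1e-12:
            ib += 1
        h_try = h
        if h_try > hcap:
            h_try = hcap
        if t + h_try > t_end:
            h_try = t_end - t
        if ib < nb and t + h_try > breaks[ib]:
            h_try = breaks[ib] - t
        if h_try < 1e-12:
            status = STEP_UNDERFLOW
            break

        # stage 0 at the step start (recomputed each step: lagged values may
        # be discontinuous across break points)
        _stage_rhs(topo, t, y, p, ex, delays, lag_idx, hist, ts0, hs, ys, Qs, nst, y_st)
        K[0] = y_st
        for s in range(1, 6):
            for d in range(n):
                acc = 0.0
                for j in range(s):
                    acc += _A[s, j] * K[j, d]
                y_st[d] = y[d] + h_try * acc
            _stage_rhs(topo, t + _C[s] * h_try, y_st, p, ex, delays, lag_idx,
                       hist, ts0, hs, ys, Qs, nst, K[s])
        # 5th-order solution
        for d in range(n):
            acc = 0.0
            for s in range(6):
                acc += _B[s] * K[s, d]
            y_st[d] = y[d] + h_try * acc
        y_new = y_st.copy()
        _stage_rhs(topo, t + h_try, y_new, p, ex, delays, lag_idx,
                   hist, ts0, hs, ys, Qs, nst, K[6])

        # scaled RMS error
        err2 = 0.0
        finite = True
        for d in range(n):
            e = 0.0
            for s in range(7):
                e += _E[s] * K[s, d]
            e *= h_try
            ya = abs(y[d])
            yb = abs(y_new[d])
            sc = atol + rtol * (ya if ya > yb else yb)
            e /= sc
            err2 += e * e
            if not np.isfinite(y_new[d]):
                finite = False
        err = np.sqrt(err2 / n)

        if not finite or not np.isfinite(err):
            h *= 0.2
            if h < 1e-12:
                status = NONFINITE_STATE
                break
            continue

        if err <= 1.0:
            # accept: store dense coefficients Q = K^T P
            ts0[nst] = t
            hs[nst] = h_try
            for d in range(n):
                for j in range(4):
                    acc = 0.0
                    for s in range(7):
                        acc += K[s, d] * _P[s, j]
                    Qs[nst, d, j] = acc
            ys[nst + 1] = y_new
            nst += 1
            t += h_try
            y = y_new
            if err == 0.0:
                fac = 10.0
            else:
                fac = 0.9 * err ** err_exp
                if fac > 10.0:
                    fac = 10.0
            h = h_try * fac
        else:
            fac = 0.9 * err ** err_exp
            if fac < 0.2:
                fac = 0.2
            h = h_try * fac
            if h < 1e-12:
                status = STEP_UNDERFLOW
                break

    if status == OK:
        for i in range(neval):
            s = t_eval[i]
            for d in range(n):
                y_eval[i, d] = _sol_comp(s, d, hist, ts0, hs, ys, Qs, nst)
    return y_eval, status


@njit(cache=True)
def _rhs_once(topo, t, y, lagc, lagdp, p, ex):
    out = np.empty(y.shape[0])
    _rhs(topo, t, y, lagc, lagdp, p, ex, out)
    return out
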