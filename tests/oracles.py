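"""Independent oracles used by the test suite.

Two deliberately separate implementations of the model:

* exact-arithmetic transcriptions of every right-hand side using
  ``fractions.Fraction`` (no shared code with the package kernels), each
  returning the derivative together with a per-component term-magnitude
  scale so relative comparisons remain meaningful near cancellations;
* a fixed-step Heun (explicit trapezoidal) method-of-steps integrator for
  the coarse model, with lags resolved on the step grid.
"""

from __future__ import annotations

from fractions import Fraction as F

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# exact transcriptions (coarse / detailed / alternative topologies)
# ---------------------------------------------------------------------------


def _fr(x):
    return F(float(x))


def _sum_terms(terms):
    val = sum(terms, start=F(0))
    scale = sum((abs(t) for t in terms), start=F(0))
    return val, scale


def rhs_coarse_exact(state, lagc, lagdp, p):
    """Exact coarse-model derivative; returns (values, term scales) as floats.

    ``p`` is a mapping with the coarse parameter names; state order is
    [DN, DP, cTEC, SP4, mTEC].
    """
    DN, DP, C, S, M = map(_fr, state)
    lc, ld = _fr(lagc), _fr(lagdp)
    g = {k: _fr(v) for k, v in p.items()}
    rows = [
        [g["phi1"], g["delta1"] * DN, -g["mu1"] * C * DN],
        [g["mu1"] * g["r1"] * C * DN,
         g["theta2"] * DP, -g["theta2"] * DP * DP / g["K2"], -g["mu2"] * lc * DP],
        [g["phic"], -g["deltac"] * C, g["muc"] * DN * C],
        [g["mu2"] * g["r24"] * lc * DP, -g["mu4"] * M * S],
        [g["phim"], g["phim4"] * S,
         g["rm"] * M, -g["rm"] * M * M / g["Km"], -g["gammamp"] * ld * M],
    ]
    vals, scales = zip(*(_sum_terms(r) for r in rows))
    return np.array([float(v) for v in vals]), np.array([float(s) for s in scales])


def rhs_detailed_exact(state, lagc, p, verbatim=False):
    """Exact detailed-model derivative; state order [DN1..DN4, DP, cTEC]."""
    D1, D2, D3, D4, DP, C = map(_fr, state)
    lc = _fr(lagc)
    g = {k: _fr(v) for k, v in p.items()}
    Ds = [D1, D2, D3, D4]
    sgn = F(1) if verbatim else F(-1)
    rows = [[g["phi1"], g["deltaDN1"] * D1, -g["muDN1"] * C * D1]]
    for i in (2, 3, 4):
        rows.append([
            g[f"muDN{i-1}"] * C * Ds[i - 2],
            g[f"deltaDN{i}"] * Ds[i - 1],
            sgn * g[f"muDN{i}"] * C * Ds[i - 1],
        ])
    rows.append([
        g["rDN4"] * g["muDN4"] * C * D4,
        g["theta2"] * DP, -g["theta2"] * DP * DP / g["K2"], -g["mu2"] * lc * DP,
    ])
    rows.append([g["phic"], -g["deltac"] * C]
                + [g[f"muCTEC{j}"] * Ds[j - 1] * C for j in (1, 2, 3, 4)])
    vals, scales = zip(*(_sum_terms(r) for r in rows))
    return np.array([float(v) for v in vals]), np.array([float(s) for s in scales])


def rhs_alternative_exact(variant, state, lagc, lagdp, p):
    """Exact derivative of topologies M1-M4 (only one equation differs)."""
    DN, DP, C, S, M = map(_fr, state)
    lc, ld = _fr(lagc), _fr(lagdp)
    g = {k: _fr(v) for k, v in p.items()}
    base_vals, base_scales = rhs_coarse_exact(state, lagc, lagdp, p)
    if variant == "M1":
        row = [g["phim"], g["phim4"] * S, -g["gammamp"] * ld * M, -g["mum"] * M]
        idx = 4
    elif variant == "M2":
        row = [g["phimn"] * DN, g["phim4"] * S, -g["mum"] * M]
        idx = 4
    elif variant == "M3":
        row = [g["mu1"] * g["r1"] * C * DN,
               g["r2"] * DP, -g["r2"] * DP * DP / g["K2"], g["mu2"] * C * DP]
        idx = 1
    elif variant == "M4":
        row = [g["phic"], -g["deltac"] * C, g["muc"] * DN * C, -g["gammac"] * ld * C]
        idx = 2
    else:
        raise ValueError(variant)
    v, s = _sum_terms(row)
    base_vals[idx], base_scales[idx] = float(v), float(s)
    return base_vals, base_scales


# ---------------------------------------------------------------------------
# fixed-step Heun method-of-steps integrator (coarse model)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _heun_rhs(y, lagc, lagdp, p, out):
    # independent transcription of the coarse equations
    out[0] = p[0] + (p[1] - p[2] * y[2]) * y[0]
    out[1] = p[2] * p[3] * y[2] * y[0] + (p[4] * (1.0 - y[1] / p[5]) - p[6] * lagc) * y[1]
    out[2] = p[10] + (-p[11] + p[12] * y[0]) * y[2]
    out[3] = p[6] * p[8] * lagc * y[1] - p[9] * y[4] * y[3]
    out[4] = p[13] + p[14] * y[3] + (p[15] * (1.0 - y[4] / p[16]) - p[17] * lagdp) * y[4]


@njit(cache=True)
def heun_coarse(p, y0, hist, h, n_steps, out_every):
    """Fixed-step Heun over n_steps steps of size h.

    Lags tau2 (cTEC) and taum (DP) must be integer multiples of h; history
    before t = 0 is the constant ``hist`` vector.  Returns the state at
    every ``out_every``-th grid point (including t = 0).
    """
    L2 = int(round(p[7] / h))
    Lm = int(round(p[18] / h))
    c_hist = np.empty(n_steps + 1)
    d_hist = np.empty(n_steps + 1)
    y = y0.copy()
    c_hist[0] = y[2]
    d_hist[0] = y[1]
    n_out = n_steps // out_every + 1
    out = np.empty((n_out, 5))
    out[0] = y
    k1 = np.empty(5)
    k2 = np.empty(5)
    ytmp = np.empty(5)
    for k in range(n_steps):
        i1 = k - L2
        lagc = hist[2] if i1 < 0 else c_hist[i1]
        i2 = k - Lm
        lagdp = hist[1] if i2 < 0 else d_hist[i2]
        _heun_rhs(y, lagc, lagdp, p, k1)
        for d in range(5):
            ytmp[d] = y[d] + h * k1[d]
        j1 = k + 1 - L2
        lagc2 = hist[2] if j1 < 0 else c_hist[j1] if j1 <= k else ytmp[2]
        j2 = k + 1 - Lm
        lagdp2 = hist[1] if j2 < 0 else d_hist[j2] if j2 <= k else ytmp[1]
        _heun_rhs(ytmp, lagc2, lagdp2, p, k2)
        for d in range(5):
            y[d] = y[d] + 0.5 * h * (k1[d] + k2[d])
        c_hist[k + 1] = y[2]
        d_hist[k + 1] = y[1]
        if (k + 1) % out_every == 0:
            out[(k + 1) // out_every] = y
    return out
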