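"""DDE integration: closed forms, oracle equivalence, interpolation, invariants."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thymocross import (
    CoarseParams,
    IrradiationModel,
    SimulationSpec,
    Trajectory,
    observe,
    simulate,
)
from thymocross.params import COARSE_TYPES

from oracles import heun_coarse


def _irr(n0, p, omega):
    return IrradiationModel(COARSE_TYPES, n_tot0=np.full(5, n0),
                            p=np.full(5, p), omega=np.full(5, omega))


def test_linear_closed_form():
    """With all interactions off and delta1 < 0, DN follows the scalar linear ODE
    n(t) = phi/|delta| + (p*n0 - phi/|delta|) * exp(delta * t)."""
    # delta1 < 0 is outside the non-negative parameter container, so emulate
    # the net negative self-rate with a removal term against a constant cTEC
    # pool: delta1 - mu1*cTEC = -0.4 exactly, cTEC held constant by
    # phic = deltac = muc = 0 and cTEC(0) = n0 (p_cTEC = 1).
    n0 = 1.0e4
    params = CoarseParams(phi1=500.0, delta1=0.1, mu1=0.5 / n0, K2=1e8, Km=1e5)
    irr = IrradiationModel(COARSE_TYPES, n_tot0=np.full(5, n0),
                           p=np.array([0.3, 1.0, 1.0, 1.0, 1.0]),
                           omega=np.full(5, 1.0))
    grid = np.linspace(0, 30, 301)
    # small test population: tighten the absolute tolerance accordingly
    traj = simulate(SimulationSpec(params=params, irr=irr, grid=grid,
                                   rtol=1e-10, atol=1e-6))
    delta = 0.1 - 0.5  # net DN rate against the constant cTEC pool
    expected = 500.0 / 0.4 + (0.3 * n0 - 500.0 / 0.4) * np.exp(delta * grid)
    assert np.max(np.abs(traj.n[:, 0] - expected) / expected) < 1e-6


def test_zero_delay_equals_ode(truth_params, truth_irr):
    """With tau2 = taum = 0 the DDE degenerates to an ODE; compare against
    scipy's solve_ivp on the same undelayed system."""
    from thymocross.models import undelayed_rhs

    p0 = truth_params.replace(tau2=0.0, taum=0.0)
    grid = np.linspace(0, 30, 61)
    traj = simulate(SimulationSpec(params=p0, irr=truth_irr, grid=grid, rtol=1e-10))
    sol = solve_ivp(lambda t, y: undelayed_rhs(p0, y), (0, 30),
                    truth_irr.survivors0(), t_eval=grid, rtol=1e-10, atol=1e-4,
                    method="RK45")
    assert sol.success
    rel = np.abs(traj.n - sol.y.T) / np.maximum(np.abs(sol.y.T), 1.0)
    assert np.max(rel) < 1e-6


def test_method_of_steps_oracle(truth_params, truth_irr):
    """Adaptive solution matches a fixed-step Heun method-of-steps integrator
    (three random parameter sets here; the full ten-set sweep runs in the
    acceptance suite)."""
    rng = np.random.default_rng(17)
    h = 1e-4
    base = truth_params.to_dict()
    for _ in range(3):
        vals = {k: v * rng.uniform(0.8, 1.25) for k, v in base.items()}
        vals["r1"] = min(vals["r1"], 1.0)
        vals["r24"] = min(vals["r24"], 1.0)
        vals["tau2"] = rng.choice([1.5, 2.0, 2.5])
        vals["taum"] = rng.choice([2.5, 3.0, 3.5])
        params = CoarseParams(**vals)
        irr = truth_irr
        grid = np.arange(0.0, 20.0 + 1e-9, 0.5)
        traj = simulate(SimulationSpec(params=params, irr=irr, grid=grid))
        n_steps = int(round(20.0 / h))
        out_every = int(round(0.5 / h))
        oracle = heun_coarse(params.to_array(), irr.survivors0(),
                             irr.n_tot0.astype(float), h, n_steps, out_every)
        rel = np.abs(traj.n - oracle) / np.maximum(np.abs(oracle), 1.0)
        assert np.max(rel) < 1e-3


def test_tolerance_refinement(truth_params, truth_irr):
    """The solution is tolerance-converged: halving the default tolerances
    moves every reported count by a negligible relative amount (local
    per-step tolerances amplify along the trajectory, so the bound is on the
    relative global change)."""
    grid = np.linspace(0, 49, 99)
    a = simulate(SimulationSpec(params=truth_params, irr=truth_irr, grid=grid,
                                rtol=1e-8, atol=1e-2))
    b = simulate(SimulationSpec(params=truth_params, irr=truth_irr, grid=grid,
                                rtol=5e-9, atol=5e-3))
    rel = np.abs(a.n_tot - b.n_tot) / np.maximum(np.abs(b.n_tot), 1.0)
    assert np.max(rel) < 1e-5


def test_trajectory_invariants(truth_params, truth_irr):
    grid = np.linspace(0, 49, 200)
    traj = simulate(SimulationSpec(params=truth_params, irr=truth_irr, grid=grid))
    assert np.allclose(traj.n_tot, traj.n + traj.n_x)
    assert np.all(traj.n >= 0)
    assert np.all(traj.n_x >= 0)


def test_overshoot_in_default_regime(truth_params, truth_irr):
    """DP and mTEC show an interior maximum above their terminal value."""
    grid = np.linspace(0, 49, 981)
    traj = simulate(SimulationSpec(params=truth_params, irr=truth_irr, grid=grid))
    for ct in ("DP", "mTEC"):
        col = traj.column(ct)
        k = int(np.argmax(col))
        assert 0 < k < len(col) - 1
        assert col[-1] < col[k]


def test_grid_validation(truth_params, truth_irr):
    with pytest.raises(ValueError, match="strictly increasing"):
        SimulationSpec(params=truth_params, irr=truth_irr, grid=np.array([0.0, 2.0, 1.0]))
    with pytest.raises(ValueError, match="t >= 0"):
        SimulationSpec(params=truth_params, irr=truth_irr, grid=np.array([-1.0, 1.0]))


@pytest.fixture(scope="module")
def traj(truth_params, truth_irr):
    grid = np.linspace(0, 49, 491)
    return simulate(SimulationSpec(params=truth_params, irr=truth_irr, grid=grid))


class TestObserve:
    def test_grid_day_is_exact(self, traj):
        tab = observe(traj, [10.0])
        j = list(traj.t).index(10.0)
        for i, ct in enumerate(traj.cell_types):
            row = tab[(tab.cell_type == str(ct))]
            assert row.n_tot.iloc[0] == pytest.approx(traj.n_tot[j, i], rel=1e-12)

    def test_day_zero_recovers_preirradiation_count(self, traj, truth_irr):
        tab = observe(traj, [0.0])
        for i, ct in enumerate(traj.cell_types):
            got = tab[tab.cell_type == str(ct)].n_tot.iloc[0]
            assert got == pytest.approx(truth_irr.n_tot0[i], rel=1e-9)

    def test_midpoint_is_arithmetic_mean(self, truth_params, truth_irr):
        # a 2-point grid forces a single linear segment
        grid = np.array([10.0, 12.0])
        t2 = simulate(SimulationSpec(params=truth_params, irr=truth_irr, grid=grid))
        tab = observe(t2, [11.0])
        for i, ct in enumerate(t2.cell_types):
            want = 0.5 * (t2.n_tot[0, i] + t2.n_tot[1, i])
            got = tab[tab.cell_type == str(ct)].n_tot.iloc[0]
            assert got == pytest.approx(want, rel=1e-12)

    def test_extrapolation_rejected(self, traj):
        with pytest.raises(ValueError, match="span"):
            observe(traj, [50.0])


def test_trajectory_tidy_export(truth_params, truth_irr):
    grid = np.linspace(0, 5, 11)
    traj = simulate(SimulationSpec(params=truth_params, irr=truth_irr, grid=grid))
    df = traj.to_frame()
    assert set(df.columns) == {"day", "cell_type", "n", "n_x", "n_tot"}
    assert len(df) == 11 * 5
    assert np.allclose(df["n_tot"], df["n"] + df["n_x"])
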