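"""Objective construction, fitting, two-stage estimation, substitutions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from thymocross import (
    FitProblem,
    NoiseModel,
    Topology,
    default_detailed_irradiation,
    default_detailed_truth,
    fit,
    fit_detailed_two_stage,
    generate,
    substitute_and_resimulate,
)
from thymocross.estimation import default_values, objective, SHARED_DETAILED
from conftest import RECOVERY_FREE

DN_STAGE_FREE = ["deltaDN1", "deltaDN2", "deltaDN3", "deltaDN4",
                 "muDN1", "muDN2", "muDN3", "muDN4", "rDN4"]


class TestObjective:
    def test_zero_at_generating_truth(self, noisefree_data, truth_values):
        prob = FitProblem(Topology.COARSE, noisefree_data, truth_values,
                          free=RECOVERY_FREE)
        assert objective(prob.theta_c0(), prob) < 1e-6

    def test_single_observation_ln_e(self, truth_params, truth_irr, truth_values):
        """One observation equal to e times the model count gives objective 1."""
        from thymocross import SimulationSpec, simulate

        traj = simulate(SimulationSpec(params=truth_params, irr=truth_irr,
                                       grid=np.array([0.0, 7.0])))
        ntot7 = traj.column("DP")[-1]
        df = pd.DataFrame({"day": [7.0], "cell_type": ["DP"], "replicate": [1],
                           "count": [np.e * ntot7]})
        prob = FitProblem(Topology.COARSE, df, truth_values, free=["theta2"])
        assert objective(prob.theta_c0(), prob) == pytest.approx(1.0, abs=1e-5)

    def test_hand_summed_residuals(self, truth_params, truth_irr, truth_values):
        """Objective equals an independently summed set of log residuals."""
        data = generate(truth_params, truth_irr, noise=NoiseModel(0.3), seed=2)
        prob = FitProblem(Topology.COARSE, data, truth_values, free=["theta2"])
        # independent residual summation from the trajectory and the raw table
        from thymocross import SimulationSpec, observe, simulate

        days = np.unique(data["day"])
        traj = simulate(SimulationSpec(params=truth_params, irr=truth_irr,
                                       grid=days, rtol=prob.rtol, atol=prob.atol))
        tab = observe(traj, days)
        lut = {(r.day, r.cell_type): r.n_tot for r in tab.itertuples()}
        want = sum(
            (np.log(lut[(row.day, row.cell_type)]) - np.log(row["count"])) ** 2
            for _, row in data.iterrows())
        assert objective(prob.theta_c0(), prob) == pytest.approx(want, rel=1e-6)

    def test_nonpositive_counts_rejected(self, noisefree_data, truth_values):
        bad = noisefree_data.copy()
        bad.loc[0, "count"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            FitProblem(Topology.COARSE, bad, truth_values, free=["theta2"])

    def test_failed_simulation_returns_finite_penalty(self, noisefree_data,
                                                      truth_values):
        vals = dict(truth_values)
        prob = FitProblem(Topology.COARSE, noisefree_data, vals, free=["theta2"],
                          guess={"theta2": 1.7}, bounds={"theta2": (1.7, 1e7)})
        # an absurd proliferation rate blows the system up; the objective must
        # stay finite so the optimizer can retreat
        val = objective(np.array([1e7]), prob)
        assert np.isfinite(val) and val > 1e4


class TestThetaDecomposition:
    def test_power_of_ten_conditioning(self, noisefree_data, truth_values):
        prob = FitProblem(Topology.COARSE, noisefree_data, truth_values,
                          free=["phi1", "r1"])
        assert prob.theta_p["phi1"] == pytest.approx(1e4 * 10 ** round(np.log10(3.3)))
        assert prob.theta_p["r1"] == 1.0          # fractions are not rescaled
        assert prob.bounds["r1"] == (0.0, 1.0)
        lo, hi = prob.bounds["phi1"]
        assert lo == pytest.approx(3.3e3) and hi == pytest.approx(3.3e5)

    def test_scale_equivariance(self, noisefree_data, truth_values):
        """Multiplying theta_p by 10 while dividing the coefficient start and
        bounds by 10 yields an identical fit."""
        free = ["theta2", "mu2"]
        base = FitProblem(Topology.COARSE, noisefree_data, truth_values, free=free,
                          guess={"theta2": 2.0, "mu2": 2e-4})
        alt = FitProblem(Topology.COARSE, noisefree_data, truth_values, free=free,
                         guess={"theta2": 2.0, "mu2": 2e-4},
                         theta_p={n: base.theta_p[n] * 10 for n in free})
        ra, rb = fit(base), fit(alt)
        for n in free:
            assert ra.values[n] == pytest.approx(rb.values[n], rel=1e-6)


class TestFit:
    def test_truth_start_stays_at_truth(self, noisefree_data, truth_values):
        prob = FitProblem(Topology.COARSE, noisefree_data, truth_values,
                          free=RECOVERY_FREE)
        res = fit(prob)
        assert res.success
        for n in RECOVERY_FREE:
            assert res.values[n] == pytest.approx(truth_values[n], rel=1e-3)

    def test_objective_not_worse_than_start(self, noisy_data, truth_values):
        prob = FitProblem(Topology.COARSE, noisy_data, truth_values,
                          free=RECOVERY_FREE,
                          guess={n: truth_values[n] * 1.4 for n in RECOVERY_FREE})
        start = objective(prob.theta_c0(), prob)
        res = fit(prob)
        assert res.objective <= start

    def test_sigma2_matches_direct_computation(self, noisy_fit):
        """sigma_i^2 = SSE_i / (m_i - 1) with replicate slots counted."""
        prob = noisy_fit.problem
        res = prob.residuals(noisy_fit.theta_c)
        for j, c in enumerate(prob._cts):
            r = res[prob._obs_type_idx == j]
            assert noisy_fit.sigma2[c] == pytest.approx(
                float(np.sum(r ** 2) / (r.size - 1)), rel=1e-12)

    def test_daymean_mode_has_one_residual_per_day(self, noisy_data, truth_values):
        prob = FitProblem(Topology.COARSE, noisy_data, truth_values,
                          free=["theta2"], replicate_mode="daymean")
        n_days = noisy_data["day"].nunique()
        assert prob.n_residuals == n_days * 5


@pytest.fixture(scope="module")
def detailed_noisefree():
    return generate(default_detailed_truth(), default_detailed_irradiation(),
                    noise=NoiseModel(0.0), seed=31)


@pytest.fixture(scope="module")
def coarse_like_result(truth_values):
    """Stand-in for a coarse fit: shared parameters at the coarse truth,
    including the large coarse-model DN influx."""
    class _R:
        values = dict(truth_values)
    return _R()


class TestTwoStage:
    def test_stage2_recovers_small_phi1(self, detailed_noisefree,
                                        coarse_like_result):
        """On detailed-model data the re-freed DN influx returns to the small
        generating value, far from the coarse-model estimate."""
        dvals = default_values(Topology.DETAILED)
        guess = {n: dvals[n] * 1.3 for n in DN_STAGE_FREE if n != "rDN4"}
        guess["rDN4"] = 0.3
        guess["phi1"] = 200.0
        prob = FitProblem(Topology.DETAILED, detailed_noisefree, dvals,
                          free=DN_STAGE_FREE + ["phi1"], guess=guess)
        two = fit_detailed_two_stage(prob, coarse_like_result)
        assert two.stage2.values["phi1"] == pytest.approx(66.0, rel=1e-2)
        assert two.stage2.values["phi1"] < 1e-2 * coarse_like_result.values["phi1"]
        # stage 1 kept the shared parameters fixed at the coarse estimates
        for n in SHARED_DETAILED:
            assert two.stage1.values[n] == coarse_like_result.values[n]

    def test_freeing_phi1_does_not_worsen_objective(self, detailed_noisefree,
                                                    coarse_like_result):
        dvals = default_values(Topology.DETAILED)
        guess = {n: dvals[n] * 1.3 for n in DN_STAGE_FREE if n != "rDN4"}
        guess["rDN4"] = 0.3
        guess["phi1"] = 200.0
        prob = FitProblem(Topology.DETAILED, detailed_noisefree, dvals,
                          free=DN_STAGE_FREE + ["phi1"], guess=guess)
        two = fit_detailed_two_stage(prob, coarse_like_result)
        assert two.stage2.objective <= two.stage1.objective + 1e-9


class TestSubstitution:
    def test_empty_override_is_identity(self, noisy_fit):
        sub = substitute_and_resimulate(noisy_fit, {})
        assert max(sub.max_rel_change.values()) == 0.0

    def test_small_phi1_leaves_trajectories_nearly_unchanged(self, noisy_fit):
        """Replacing the DN influx by a ~500-fold smaller value moves no
        compartment's trajectory by more than the 5% default threshold."""
        sub = substitute_and_resimulate(noisy_fit, {"phi1": 66.0})
        assert sub.unaffected(threshold=0.05)

    def test_unknown_override_rejected(self, noisy_fit):
        with pytest.raises(KeyError, match="unknown"):
            substitute_and_resimulate(noisy_fit, {"not_a_param": 1.0})
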