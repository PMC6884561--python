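"""Right-hand sides, the irradiation observation layer, and steady states."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from thymocross import (
    AlternativeParams,
    CoarseParams,
    DetailedParams,
    IrradiationModel,
    Topology,
    decayed_count,
    rhs_alternative,
    rhs_coarse,
    rhs_detailed,
    steady_state,
)
from thymocross.models import undelayed_rhs
from thymocross.params import COARSE_TYPES

from oracles import rhs_alternative_exact, rhs_coarse_exact, rhs_detailed_exact


def _random_coarse(rng) -> CoarseParams:
    return CoarseParams(
        phi1=rng.uniform(10, 1e5), delta1=rng.uniform(0, 2), mu1=rng.uniform(0, 1e-3),
        r1=rng.uniform(0, 1), theta2=rng.uniform(0, 3), K2=rng.uniform(1e6, 1e9),
        mu2=rng.uniform(0, 1e-3), tau2=rng.uniform(0, 4), r24=rng.uniform(0, 1),
        mu4=rng.uniform(0, 1e-4), phic=rng.uniform(0, 5e3), deltac=rng.uniform(0, 1),
        muc=rng.uniform(0, 1e-6), phim=rng.uniform(0, 1e3), phim4=rng.uniform(0, 1e-3),
        rm=rng.uniform(0, 1), Km=rng.uniform(1e3, 1e6), gammamp=rng.uniform(0, 1e-8),
        taum=rng.uniform(0, 4))


def _random_state(rng, n=5):
    return rng.uniform(1.0, 1e8, size=n)


class TestCoarseRhs:
    def test_origin_keeps_only_influxes(self):
        p = CoarseParams(phi1=7.0, phic=3.0, phim=11.0, delta1=1.0, mu1=1e-4,
                         theta2=2.0, rm=0.5, K2=1e8, Km=1e5)
        d = rhs_coarse(0.0, np.zeros(5), 0.0, 0.0, p)
        assert d == pytest.approx([7.0, 0.0, 3.0, 0.0, 11.0])

    def test_decoupled_linear_limit(self):
        p = CoarseParams(phi1=5.0, delta1=0.3, K2=1e8, Km=1e5)
        state = np.array([1e4, 2e4, 3e3, 4e3, 5e3])
        d = rhs_coarse(0.0, state, 1e4, 1e5, p)
        assert d[0] == pytest.approx(5.0 + 0.3 * 1e4, rel=1e-14)

    def test_transcription_oracle(self, truth_params):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = _random_coarse(rng)
            state, lagc, lagdp = _random_state(rng), rng.uniform(1, 1e5), rng.uniform(1, 1e8)
            got = rhs_coarse(0.0, state, lagc, lagdp, p)
            want, scale = rhs_coarse_exact(state, lagc, lagdp, p.to_dict())
            assert np.all(np.abs(got - want) <= 1e-12 * (np.abs(want) + scale))

    def test_nonfinite_input_names_component(self, truth_params):
        state = np.array([1.0, np.nan, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="state"):
            rhs_coarse(0.0, state, 1.0, 1.0, truth_params)
        with pytest.raises(ValueError, match="lagged cTEC"):
            rhs_coarse(0.0, np.ones(5), np.inf, 1.0, truth_params)

    def test_flux_bookkeeping(self, truth_params):
        """DP influx is r1 times the cTEC-dependent DN removal; SP4 influx is
        r24 times the delayed cTEC-dependent DP removal."""
        rng = np.random.default_rng(3)
        p = truth_params
        state, lagc, lagdp = _random_state(rng), 8.0e3, 1.0e8
        dn_removal = p.mu1 * state[2] * state[0]
        dp_removal_delayed = p.mu2 * lagc * state[1]
        d = rhs_coarse(0.0, state, lagc, lagdp, p)
        dp_influx = d[1] - (p.theta2 * (1 - state[1] / p.K2) - p.mu2 * lagc) * state[1]
        sp4_influx = d[3] + p.mu4 * state[4] * state[3]
        assert dp_influx == pytest.approx(p.r1 * dn_removal, rel=1e-9)
        assert sp4_influx == pytest.approx(p.r24 * dp_removal_delayed, rel=1e-12)



class TestDetailedRhs:
    def test_origin_keeps_only_influxes(self):
        p = DetailedParams(phi1=9.0, phic=4.0, K2=1e8)
        d = rhs_detailed(0.0, np.zeros(6), 0.0, p)
        assert d == pytest.approx([9.0, 0, 0, 0, 0, 4.0])

    def test_decoupled_stage_exponentials(self):
        p = DetailedParams(phi1=0.0, deltaDN1=0.1, deltaDN2=0.2, deltaDN3=0.3,
                           deltaDN4=0.4, K2=1e8)
        state = np.array([1e3, 2e3, 3e3, 4e3, 0.0, 0.0])
        d = rhs_detailed(0.0, state, 0.0, p)
        assert d[:4] == pytest.approx([0.1 * 1e3, 0.2 * 2e3, 0.3 * 3e3, 0.4 * 4e3])

    @pytest.mark.parametrize("verbatim", [False, True])
    def test_transcription_oracle(self, verbatim):
        rng = np.random.default_rng(7)
        for _ in range(20):
            vals = {
                "phi1": rng.uniform(1, 1e3),
                **{f"deltaDN{i}": rng.uniform(0, 1) for i in (1, 2, 3, 4)},
                **{f"muDN{i}": rng.uniform(0, 1e-3) for i in (1, 2, 3, 4)},
                "rDN4": rng.uniform(0, 1),
                **{f"muCTEC{j}": rng.uniform(0, 1e-6) for j in (1, 2, 3, 4)},
                "theta2": rng.uniform(0, 3), "K2": rng.uniform(1e6, 1e9),
                "mu2": rng.uniform(0, 1e-3), "tau2": rng.uniform(0, 4),
                "phic": rng.uniform(0, 5e3), "deltac": rng.uniform(0, 1),
            }
            p = DetailedParams(**vals)
            state, lagc = _random_state(rng, 6), rng.uniform(1, 1e5)
            got = rhs_detailed(0.0, state, lagc, p, verbatim=verbatim)
            want, scale = rhs_detailed_exact(state, lagc, vals, verbatim=verbatim)
            assert np.all(np.abs(got - want) <= 1e-12 * (np.abs(want) + scale))

    def test_flux_conserved_between_stages_default_sign(self):
        """The cTEC-dependent outflux of stage i reappears as influx of i+1."""
        p = DetailedParams(muDN1=1e-4, muDN2=2e-4, muDN3=3e-4, muDN4=4e-4, K2=1e8)
        state = np.array([1e4, 2e4, 3e4, 4e4, 0.0, 5e3])
        d = rhs_detailed(0.0, state, 0.0, p)
        # with delta=0 the stage derivative is influx minus outflux
        c = state[5]
        mus = [1e-4, 2e-4, 3e-4, 4e-4]
        for i in range(1, 4):
            expected = mus[i - 1] * c * state[i - 1] - mus[i] * c * state[i]
            assert d[i] == pytest.approx(expected, rel=1e-12)


class TestAlternativeRhs:
    @pytest.mark.parametrize("variant,key", [
        (Topology.M1_NO_MTEC_SELFSUPPRESSION, "M1"),
        (Topology.M2_DN_TO_MTEC, "M2"),
        (Topology.M3_CTEC_BOOSTS_DP, "M3"),
        (Topology.M4_DP_TO_CTEC, "M4"),
    ])
    def test_transcription_oracle(self, variant, key):
        rng = np.random.default_rng(11)
        for _ in range(20):
            base = _random_coarse(rng)
            p = AlternativeParams(variant=variant, base=base,
                                  mum=rng.uniform(0, 2), phimn=rng.uniform(0, 1e-2),
                                  r2=rng.uniform(0, 3), gammac=rng.uniform(0, 1e-8))
            state, lagc, lagdp = _random_state(rng), rng.uniform(1, 1e5), rng.uniform(1, 1e8)
            got = rhs_alternative(0.0, state, lagc, lagdp, p)
            want, scale = rhs_alternative_exact(key, state, lagc, lagdp, p.to_dict())
            assert np.all(np.abs(got - want) <= 1e-12 * (np.abs(want) + scale))

    def test_m4_nests_coarse_when_gammac_zero(self, truth_params):
        rng = np.random.default_rng(13)
        p = AlternativeParams(variant=Topology.M4_DP_TO_CTEC, base=truth_params,
                              gammac=0.0)
        for _ in range(5):
            state, lagc, lagdp = _random_state(rng), rng.uniform(1, 1e5), rng.uniform(1, 1e8)
            assert rhs_alternative(0.0, state, lagc, lagdp, p) == pytest.approx(
                rhs_coarse(0.0, state, lagc, lagdp, truth_params))

    def test_m2_pure_decay_without_influxes(self, truth_params):
        p = AlternativeParams(variant=Topology.M2_DN_TO_MTEC,
                              base=truth_params.replace(phim4=0.0),
                              mum=0.4, phimn=0.0)
        state = np.array([0.0, 0.0, 0.0, 0.0, 2.0e4])
        d = rhs_alternative(0.0, state, 0.0, 0.0, p)
        assert d[4] == pytest.approx(-0.4 * 2.0e4, rel=1e-14)

    def test_unknown_variant_rejected(self, truth_params):
        with pytest.raises(ValueError, match="variant"):
            AlternativeParams(variant=Topology.COARSE, base=truth_params)


class TestDecayedCount:
    def test_examples(self):
        irr = IrradiationModel(COARSE_TYPES,
                               n_tot0=[100.0, 1.0, 1.0, 1.0, 1.0],
                               p=[0.4, 1.0, 0.0, 0.5, 0.5],
                               omega=[0.7, 1.0, 2.0, 1.0, 1.0])
        assert decayed_count(0.0, irr, "DN") == pytest.approx(60.0)
        # fully surviving compartment has no dying pool
        assert decayed_count(3.0, irr, "DP") == 0.0
        # half-life identity at p = 0
        assert decayed_count(np.log(2) / 2.0, irr, "cTEC") == pytest.approx(0.5)
        # before irradiation the dying pool does not exist
        assert decayed_count(-1.0, irr, "DN") == 0.0


class TestSteadyState:
    def test_closed_form_decoupled_ctec(self, truth_params, truth_irr):
        # delta1 lowered so the DN compartment stays stable once the
        # DN-to-cTEC feedback is cut; guess from the default long simulation
        p = truth_params.replace(muc=0.0, delta1=0.2)
        ss = steady_state(p, irr=truth_irr)
        assert ss.converged
        assert ss.x[2] == pytest.approx(p.phic / p.deltac, rel=1e-8)

    def test_root_annihilates_rhs(self, truth_params, truth_steady):
        f = undelayed_rhs(truth_params, truth_steady)
        assert np.max(np.abs(f) / np.maximum(truth_steady, 1.0)) < 1e-8

    def test_long_simulation_agrees(self, truth_params, truth_irr, truth_steady):
        ss = steady_state(truth_params, irr=truth_irr)  # guess from long run
        assert ss.converged
        assert ss.x == pytest.approx(truth_steady, rel=1e-5)

    def test_guess_must_be_positive(self, truth_params):
        with pytest.raises(ValueError, match="positive"):
            steady_state(truth_params, np.array([1.0, -1.0, 1.0, 1.0, 1.0]))


@given(st.floats(0.01, 0.99), st.floats(0.1, 3.0), st.floats(10.0, 1e6))
def test_observation_decomposition_sums_to_baseline_at_zero(p, omega, n0):
    """n(0) + n_x(0) = p*n0 + (1-p)*n0 = the pre-irradiation count."""
    irr = IrradiationModel(COARSE_TYPES, n_tot0=[n0] * 5, p=[p] * 5, omega=[omega] * 5)
    total = irr.survivors0()[0] + irr.decayed(0.0, "DN")
    assert total == pytest.approx(n0, rel=1e-12)
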