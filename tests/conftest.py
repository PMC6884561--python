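"""Shared fixtures: the default truth regime and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from thymocross import (
    FitProblem,
    NoiseModel,
    Topology,
    default_coarse_truth,
    default_irradiation,
    fit,
    generate,
    steady_state,
)
from thymocross.estimation import default_values

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: free-parameter set used by the reduced-scale estimation studies
RECOVERY_FREE = ["phi1", "delta1", "mu1", "theta2", "K2", "mu2", "mu4"]


@pytest.fixture(scope="session")
def truth_params():
    return default_coarse_truth()


@pytest.fixture(scope="session")
def truth_irr():
    return default_irradiation()


@pytest.fixture(scope="session")
def truth_values():
    return default_values(Topology.COARSE)


@pytest.fixture(scope="session")
def truth_steady(truth_params, truth_irr):
    ss = steady_state(truth_params, truth_irr.n_tot0)
    assert ss.converged
    return ss.x


@pytest.fixture(scope="session")
def noisefree_data(truth_params, truth_irr):
    return generate(truth_params, truth_irr, noise=NoiseModel(0.0), seed=1)


@pytest.fixture(scope="session")
def noisy_data(truth_params, truth_irr):
    return generate(truth_params, truth_irr, noise=NoiseModel(0.2), seed=7)


@pytest.fixture(scope="session")
def noisy_fit(noisy_data, truth_values):
    problem = FitProblem(Topology.COARSE, noisy_data, truth_values,
                         free=RECOVERY_FREE)
    result = fit(problem)
    assert result.success
    return result
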