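"""Fit the crosstalk model to synthetic counts and derive kinetic quantities.

Fits seven parameters (DN influx and self-rate, the DN and DP removal
couplings, the DP logistic terms, the SP4 export coupling) by log-space
least squares from deliberately wrong starting guesses (1.5x the truth),
then reports the literature-comparable composite quantities evaluated at the
fitted steady state.
"""

from thymocross import (
    FitProblem,
    NoiseModel,
    Topology,
    default_coarse_truth,
    default_irradiation,
    derive,
    fit,
    generate,
    steady_state,
)
from thymocross.estimation import default_values

FREE = ["phi1", "delta1", "mu1", "theta2", "K2", "mu2", "mu4"]

truth = default_coarse_truth()
irr = default_irradiation()
values = default_values(Topology.COARSE)

data = generate(truth, irr, noise=NoiseModel(0.0), seed=1)  # noise-free
problem = FitProblem(Topology.COARSE, data, values, free=FREE,
                     guess={n: values[n] * 1.5 for n in FREE})
result = fit(problem)
print(f"converged={result.success}, objective={result.objective:.2e}, "
      f"nfev={result.nfev}")

truth_dq = derive(truth, steady_state(truth, irr.n_tot0).x).to_dict()
fit_dq = derive(result.params, steady_state(result.params, irr.n_tot0).x).to_dict()
print(f"\n{'composite quantity':30s}{'truth':>12s}{'fitted':>12s}")
for k in truth_dq:
    print(f"{k:30s}{truth_dq[k]:12.4g}{fit_dq[k]:12.4g}")
print("\nOn noise-free data the optimizer returns to the generating values,")
print("so every composite (rates in 1/day, residence times in hours, the")
print("DP-to-SP4 fraction in %) matches the truth to fractions of a percent.")
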