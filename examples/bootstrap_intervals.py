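"""Parametric bootstrap confidence intervals for the fitted parameters.

Refits the model to noise resamples drawn around the fitted trajectory
(Gaussian on the log scale, variances estimated from the residuals) and
reports percentile intervals.  The DN influx phi1 illustrates weak
identifiability: its resampled estimates scatter over orders of magnitude
while well-identified parameters stay tight.
"""

from thymocross import (
    FitProblem,
    NoiseModel,
    Topology,
    default_coarse_truth,
    default_irradiation,
    fit,
    generate,
    run_bootstrap,
)
from thymocross.estimation import default_values

FREE = ["phi1", "delta1", "mu1", "theta2", "mu2", "mu4"]

values = default_values(Topology.COARSE)
data = generate(default_coarse_truth(), default_irradiation(),
                noise=NoiseModel(0.2), seed=21)
result = fit(FitProblem(Topology.COARSE, data, values, free=FREE))
boot = run_bootstrap(result, B=50, alpha=0.95, seed=5)

print(boot.interval_frame().to_string(index=False,
                                      float_format=lambda x: f"{x:.4g}"))
k = boot.parameters.index("phi1")
ph = boot.samples[boot.converged, k]
print(f"\nphi1 resamples span {ph.min():.3g} .. {ph.max():.3g} "
      f"({ph.max() / ph.min():.0f}-fold): the DN influx is weakly identified")
print("because DN recovery is dominated by proliferation, not influx; its")
print("interval spans the whole factor-of-ten search range, mirroring the")
print("multimodal influx estimates seen in bootstrap analyses of such data.")
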