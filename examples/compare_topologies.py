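"""Compare alternative crosstalk network topologies on the same dataset.

Fits the reference model, the variant with a DP-to-cTEC suppression (which
nests the reference model), and the variant without mTEC self-suppression,
then prints the rejection diagnostics used during model identification.
"""

import json

from thymocross import (
    FitProblem,
    NoiseModel,
    Topology,
    compare_topologies,
    default_coarse_truth,
    default_irradiation,
    generate,
)
from thymocross.estimation import default_values

data = generate(default_coarse_truth(), default_irradiation(),
                noise=NoiseModel(0.1), seed=23)

m4 = default_values(Topology.M4_DP_TO_CTEC)
m4["gammac"] = 1e-10
m1 = default_values(Topology.M1_NO_MTEC_SELFSUPPRESSION)
m1["mum"] = 0.3
problems = [
    FitProblem(Topology.COARSE, data, default_values(Topology.COARSE),
               free=["muc", "delta1", "theta2"]),
    FitProblem(Topology.M4_DP_TO_CTEC, data, m4,
               free=["gammac", "muc", "delta1", "theta2"]),
    FitProblem(Topology.M1_NO_MTEC_SELFSUPPRESSION, data, m1,
               free=["mum", "gammamp", "phim4"]),
]
report = compare_topologies(problems)
print(json.dumps(report.outcomes, indent=2, default=float))
print("\nReading the diagnostics: the nested DP-to-cTEC coupling is estimated")
print("near zero (zeroing it barely moves the trajectories -> the extra arrow")
print("is unsupported), and the no-self-suppression variant is judged by the")
print("mTEC lifetime its fitted loss rate implies (hours-scale lifetimes are")
print("implausible for epithelial cells).")
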