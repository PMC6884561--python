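"""Two-stage estimation of the DN1-DN4 detailed model.

Stage 1 fixes the parameters shared with the coarse model (including the DN
influx phi1) to the coarse estimates and fits the per-stage rates; stage 2
re-frees phi1 with a small, biologically motivated starting guess.  On data
generated by the detailed model the re-freed influx returns to the small
generating value — hundreds of times below the coarse-model estimate —
showing that stage-resolved data discriminate what aggregated DN counts
cannot.
"""

from thymocross import (
    FitProblem,
    NoiseModel,
    Topology,
    default_detailed_irradiation,
    default_detailed_truth,
    fit_detailed_two_stage,
    generate,
)
from thymocross.estimation import default_values

DN_FREE = ["deltaDN1", "deltaDN2", "deltaDN3", "deltaDN4",
           "muDN1", "muDN2", "muDN3", "muDN4", "rDN4"]

truth = default_detailed_truth()          # phi1 = 66 cells/day
data = generate(truth, default_detailed_irradiation(),
                noise=NoiseModel(0.0), seed=31)

values = default_values(Topology.DETAILED)
guess = {n: values[n] * 1.3 for n in DN_FREE if n != "rDN4"}
guess["rDN4"] = 0.3
guess["phi1"] = 200.0                     # progenitor-influx prior, not the coarse value


class CoarseStandIn:
    """Shared parameters as a coarse fit would deliver them (phi1 = 3.3e4)."""
    values = default_values(Topology.COARSE)


problem = FitProblem(Topology.DETAILED, data, values,
                     free=DN_FREE + ["phi1"], guess=guess)
two = fit_detailed_two_stage(problem, CoarseStandIn())

print(f"stage 1 (phi1 fixed at coarse {CoarseStandIn.values['phi1']:.3g}): "
      f"objective {two.stage1.objective:.3g}")
print(f"stage 2 (phi1 re-freed from guess 200): "
      f"objective {two.stage2.objective:.3g}, phi1 = {two.stage2.values['phi1']:.3g}")
print(f"generating value: {truth.phi1}")
print("\nThe coarse-model influx cannot reproduce the DN1 kinetics; once freed,")
print("phi1 drops by ~500x to the generating value, while the stage rates and")
print("the shared DP/cTEC parameters stay at their fixed coarse estimates.")
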