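"""Simulate post-irradiation recovery of thymocytes and TECs.

Integrates the five-compartment crosstalk model (DN, DP, SP4 thymocytes;
cTECs, mTECs) from the post-irradiation state and summarizes the recovery
shape of the observable counts n_tot = surviving/regenerating cells plus the
exponentially dying irradiated pool.
"""

import numpy as np

from thymocross import SimulationSpec, default_coarse_truth, default_irradiation, simulate

params = default_coarse_truth()
irr = default_irradiation()
grid = np.linspace(0.0, 49.0, 981)
traj = simulate(SimulationSpec(params=params, irr=irr, grid=grid))

print("compartment   onset[d]  peak[d]  peak/baseline  day49/baseline")
for j, ct in enumerate(traj.cell_types):
    col = traj.n_tot[:, j]
    onset = next(i for i in range(1, len(col) - 1)
                 if col[i] <= col[i - 1] and col[i] < col[i + 1])
    k = int(np.argmax(col))
    print(f"{str(ct):12s} {grid[onset]:8.1f} {grid[k]:8.1f} "
          f"{col[k] / irr.n_tot0[j]:14.2f} {col[-1] / irr.n_tot0[j]:15.2f}")

print("\nEach compartment crashes after irradiation, turns around within a few")
print("days (onset), and DP/mTEC overshoot their baseline before settling —")
print("the signature of the delayed negative feedbacks in the crosstalk network.")
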