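"""Per-monomer state dynamics: populations and transition probabilities.

Simulates a fiber whose monomers exchange between ordered / defect /
adsorbed states according to a planted Markov matrix, then re-estimates that
matrix from the per-monomer state sequences.
"""

import numpy as np

from defectometer import SyntheticSpec, generate, transition_matrix
from defectometer.dynamics import StateTrajectory, interconversion_matrix

P = np.array([[0.95, 0.04, 0.01],
              [0.30, 0.60, 0.10],
              [0.10, 0.20, 0.70]])
asm = generate(SyntheticSpec(kind="fiber", n_monomers=100, n_frames=1000,
                             planted_P=P, seed=21))
tm = transition_matrix(StateTrajectory(labels=asm.labels), lag=1)

print("planted transition matrix:")
print(np.round(P, 3))
print("recovered from state sequences (1-frame lag):")
print(np.round(tm.P, 3))
print(f"max per-entry error: {np.abs(tm.P - P).max():.4f}")
print(f"equilibrium populations: {np.round(tm.populations, 3)}")
print("interconversion (self-transitions removed, rows renormalized):")
print(np.round(interconversion_matrix(tm), 3))
# With 100 monomers x 1000 frames (1e5 observations) every transition
# probability is recovered to about +/-0.01.
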