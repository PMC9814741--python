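"""Compute per-monomer SOAP descriptors for a synthetic fiber.

Builds a small 1-D stack with planted defects, computes the 324-component
SOAP power spectrum of every monomer environment, and shows that ordered and
defect monomers occupy visibly different regions of descriptor space.
"""

import numpy as np

from defectometer import SoapParams, SyntheticSpec, generate, soap_trajectory

asm = generate(SyntheticSpec(kind="fiber", n_monomers=100, n_frames=5, seed=1,
                             state_fractions=(0.85, 0.10, 0.05)))
params = SoapParams(nmax=8, lmax=8, rcut=0.8)  # cutoff in nm
spectra, _ = soap_trajectory(asm.trajectory, params)
print(f"spectra shape (frames, monomers, D): {spectra.shape}")

labels = asm.labels[:, 0]
for state, name in enumerate(asm.state_names):
    norms = np.linalg.norm(spectra[0, labels == state], axis=1)
    print(f"{name:>9s}: {np.sum(labels == state):3d} monomers, "
          f"|p| = {norms.mean():.4f} +/- {norms.std():.4f}")

# The descriptor norm tracks how much neighbour density a monomer sees:
# ordered monomers (two stack contacts) > defects (one side contact) >
# adsorbed monomers (no contact, self term only).
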