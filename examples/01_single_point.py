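"""Single-point calculation on an analytic diabatic model.

Builds a two-state linear-vibronic-coupling model, runs it through the
standard interface lifecycle, and prints the adiabatic energies and the
upper-state gradient.  The same QMout can be written to the text dialect
for standalone use.
"""

import numpy as np

import esi
from esi.containers import RequestSet

# two coupled states over one "atom" (3 coordinates), energies in Hartree
model = esi.DiabaticModel(
    r0=np.zeros(3),
    k=0.5,                              # harmonic force constant, Eh/Bohr^2
    epsilon=[0.0, 0.15],                # diabatic energy offsets
    kappa=[[0.05, 0, 0], [-0.05, 0, 0]],  # state-specific linear slopes
    lam=[[0.0, 0.02], [0.02, 0.0]],     # constant interstate coupling
)

iface = esi.LVCModelInterface()
iface.setup_molecule(esi.model_molecule(model))
iface.read_template({"model_object": model})
iface.read_resources(None)
iface.finalize()

R = np.array([[0.3, 0.0, 0.0]])  # Bohr
out = iface.single_point(R, RequestSet(hamiltonian=True, gradients="all", step=0))

print("adiabatic energies / Eh :", np.array2string(out.energies, precision=6))
print("S2 gradient / Eh Bohr^-1:", np.array2string(out.grad[1], precision=6))
print("gap / meV               :", esi.format_mev(out.energies[1] - out.energies[0]))

esi.write_qmout(out, "scratch_single_point.QM.out")
print("wrote scratch_single_point.QM.out (text dialect, self-descriptive header)")
# The energies are the eigenvalues of the 2x2 diabatic potential matrix at R;
# the gradient is the exact Hellmann-Feynman derivative of the upper surface.
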