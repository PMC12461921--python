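"""Subtractive QM/MM with electrostatic embedding.

A 5-atom system: 2 atoms form the excited-state chromophore (QM region,
an analytic two-state model with a Stark response), 3 atoms are an MM
environment with partial charges and harmonic bonds.  The parent runs the
MM model on the full system (MML) and on the QM region (MMS), embeds the
MM charges as point charges in the QM child, and assembles total energies
and full-system gradients.
"""

import numpy as np

import esi
from esi.containers import MoleculeSpec, RequestSet

rng = np.random.default_rng(12)
qm_model = esi.random_model(rng, n_states=2, n_atoms=2)
qm_model.stark = rng.normal(0, 0.5, (2, 3))  # per-state dipoles -> embedding response
mm_model = esi.MMModel(
    5,
    bonds=[(0, 1, 0.4, 2.0), (2, 3, 0.5, 1.8), (3, 4, 0.3, 2.2)],
    charges=[0.1, -0.1, 0.3, -0.2, -0.1],
)

root = esi.QMMMInterface()
root.setup_molecule(MoleculeSpec(["C", "O", "O", "H", "H"], [2]))
root.read_template({
    "qm_child": ("lvc_model", {"model_object": qm_model}),
    "mm_child": ("mm_model", {"model_object": mm_model}),
    "qm_atoms": [0, 1],
})
root.read_resources(None)
root.finalize()

R = rng.normal(0, 1, (5, 3)) + np.arange(5)[:, None] * 2.0
R[:2] = qm_model.r0.reshape(2, 3) + 0.05
out = root.single_point(R, RequestSet(hamiltonian=True, gradients="all", step=0))

print("total energies / Eh:", np.array2string(out.energies, precision=6))
for label, value in out.prop0d:
    print(f"{label:12s}: {value: .6f} Eh")
print("gradient shape     :", out.grad.shape, "(per state, full system)")
print("max |grad| on MM atoms:", float(np.max(np.abs(out.grad[:, 2:, :]))))
# The MM terms shift all states equally (state-independent environment);
# the MM-atom gradient rows combine the MM force field with the QM child's
# forces on the embedded point charges.
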