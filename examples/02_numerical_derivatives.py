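"""Gradients and nonadiabatic couplings by overlap-based differentiation.

Wraps a model that only exposes energies and wave-function overlaps in the
numerical-differentiation hybrid; the hybrid's feature set then advertises
gradients and NAC vectors it assembles from 6*N_atom displaced child runs.
The results are compared against the model's closed-form derivatives.
"""

import numpy as np

import esi
from esi.containers import RequestSet

rng = np.random.default_rng(4)
model = esi.random_model(rng, n_states=2, n_atoms=2)

hybrid = esi.NumDiffInterface()
child = esi.LVCModelInterface(name="ref")
child._pending_template = {"model_object": model, "features": "h overlap"}
hybrid.add_child("ref", child)
hybrid.setup_molecule(esi.model_molecule(model))
hybrid.read_template({"delta": 1e-3, "scheme": "diabatic",
                      "properties": "grad nacdr"})
hybrid.read_resources(None)
hybrid.finalize()

print("child features :", sorted(child.get_features()))
print("hybrid features:", sorted(hybrid.get_features()))

R = model.r0 + 0.1
out = hybrid.single_point(
    R.reshape(-1, 3),
    RequestSet(hamiltonian=True, gradients="all", nac_vectors=True, step=0),
)

g_err = max(
    np.max(np.abs(out.grad[i].ravel() - esi.analytic_gradient(model, R, i)))
    for i in range(2)
)
n_err = np.max(np.abs(out.nacdr[0, 1].ravel() - esi.analytic_nac(model, R, 0, 1)))
print(f"max gradient error vs closed form: {g_err:.2e} Eh/Bohr")
print(f"max NAC error vs closed form     : {n_err:.2e} 1/Bohr")
# Both errors are dominated by the O(delta^2) truncation of the central
# difference; the diabatic scheme stays accurate even where the adiabatic
# states mix between the reference and displaced geometries.
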