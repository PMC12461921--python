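"""Two-stage minimum-energy conical intersection optimization.

Stage 1: the penalty method (sigma = 3.5, alpha = 0.02), which needs only
gradients and leaves a small residual gap.  Stage 2: the projected-gradient
method driven by *numerical* gradients and NAC vectors from the
differentiation hybrid over a child that exposes only energies and
overlaps — the same setup one would use with an electronic-structure
program lacking analytic couplings.  The model has an analytically known
intersection, so the recovery error is exact.
"""

import numpy as np

import esi
from esi.meci import PenaltyConfig, penalty_optimize, projected_optimize

rng = np.random.default_rng(8)
model, meci_true, _ = esi.planted_ci_model(rng)

analytic = esi.LVCModelInterface()
analytic.setup_molecule(esi.model_molecule(model))
analytic.read_template({"model_object": model})
analytic.read_resources(None)
analytic.finalize()

start = meci_true + rng.normal(0, 0.3, meci_true.shape)
pen = penalty_optimize(analytic, start, PenaltyConfig(sigma=3.5, alpha=0.02))
print(f"penalty stage : {pen.iterations:3d} iterations, "
      f"gap {pen.gap:.6f} Eh ({esi.format_mev(pen.gap)} meV)")

hybrid = esi.NumDiffInterface()
child = esi.LVCModelInterface(name="ref")
child._pending_template = {"model_object": model, "features": "h overlap"}
hybrid.add_child("ref", child)
hybrid.setup_molecule(esi.model_molecule(model))
hybrid.read_template({"delta": 1e-3, "scheme": "diabatic"})
hybrid.read_resources(None)
hybrid.finalize()

proj = projected_optimize(hybrid, pen.geometry)
print(f"projected stage: {proj.iterations:3d} iterations, "
      f"gap {proj.gap:.2e} Eh ({esi.format_mev(proj.gap)} meV)")
print(f"distance to the planted intersection: "
      f"{np.max(np.abs(proj.geometry - meci_true)):.2e} Bohr")
# The projected stage always ends with a smaller gap than the penalty
# stage; on these models it lands on the exact seam minimum.
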