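# esi — hierarchical electronic-structure interfaces for nonadiabatic dynamics

Trajectory surface-hopping simulations need, at every time step, a bundle of
electronic quantities — Hamiltonian (energies and spin–orbit couplings),
wave-function overlaps, gradients, nonadiabatic coupling (NAC) vectors,
dipole matrices — from whatever electronic-structure backend the user has.
`esi` is a library for building the *interface layer* of such simulations:

* **Standardized containers.** `QMin` collects molecule, coordinates,
  requests, save/step bookkeeping and interface-private configuration;
  `QMout` carries the results, indexed by a canonical ordering of all spin
  sublevels (a triplet contributes three sublevels duplicating the
  spin-independent data; 4 singlets + 3 triplets → 4 + 3·3 = 13 states).
  All internal units are Hartree atomic units.
* **A strict lifecycle with feature negotiation.** Every interface declares
  a feature set (`h`, `grad`, `overlap`, `nacdr`, …); requests are validated
  against it, and *hybrid* interfaces — parents that orchestrate named child
  interfaces in a nested call tree — derive their feature set from their
  children's.
* **Hybrid interfaces.** Overlap-based numerical differentiation (below),
  subtractive QM/MM with electrostatic embedding
  (`E = E_MM^large − E_MM^small + E_QM`, MM charges embedded as point
  charges, point-charge forces mapped back to MM atoms), an
  adaptive-sampling committee (leader/advisor deviation thresholds), a
  trial/backup fallback with consecutive-failure counting, and a
  transparent database recorder for active-learning data collection.
* **Analytic model backends.** Multi-state linear-vibronic-coupling models
  `W_ii = ½(R−R₀)ᵀK(R−R₀) + ε_i + κ_i·(R−R₀)`,
  `W_ij = λ_ij + μ_ij·(R−R₀)`, with closed-form adiabatic energies,
  gradients, NACs, overlaps and dipoles — every hybrid is validated against
  these exact oracles, including models with a planted conical intersection
  at an analytically known geometry.
* **Conical-intersection optimizers** driven purely through the interface
  API: the penalty method `F = (E_i+E_j)/2 + σΔE²/(ΔE+α)` (σ = 3.5,
  α = 0.02 by default) and the projected-gradient method using the
  branching plane spanned by the gradient difference and the NAC vector.
* **Analysis utilities**: classical populations of a trajectory swarm and
  binomial 95% confidence bands `P ± 1.96·√(P(1−P)/N)`.

The numerical-differentiation hybrid computes, from a reference child run
and 6·N_atom displaced runs with displacement δ (default 0.01 Bohr),

    ∂E_i/∂R_ad        = (H_ii⁺ − H_ii⁻) / 2δ                    (adiabatic)
    ⟨Ψ_i|∂Ψ_j/∂R_ad⟩ = (S_ij⁺ − S_ij⁻) / 2δ
    ∂E_i/∂R_ad        = [S⁺ᴴH⁺S⁺ − S⁻ᴴH⁻S⁻]_ii / 2δ             (diabatic)
    ⟨Ψ_i|∂Ψ_j/∂R_ad⟩ = [S⁺ᴴH⁺S⁺ − S⁻ᴴH⁻S⁻]_ij / (2δ·ΔE_ij)

where S± are overlaps between the reference and displaced wave functions.
The diabatic route stays accurate where the adiabatic states mix strongly
between reference and displaced geometries (near conical intersections).

## Worked example

Recovering a minimum-energy conical intersection with numerical gradients
and couplings from a backend that exposes only energies and overlaps
(`examples/04_meci_optimization.py`):

```bash
$ python examples/04_meci_optimization.py
penalty stage :  11 iterations, gap 0.003541 Eh (96 meV)
projected stage:   2 iterations, gap 5.00e-07 Eh (0.0 meV)
distance to the planted intersection: 2.36e-06 Bohr
```

The penalty stage (gradients only) stops near the seam with a residual gap
of a few mEh, as the smoothing parameter dictates; the projected-gradient
stage — running entirely over the numerical-differentiation hybrid —
closes the gap below 10⁻⁶ Hartree and lands on the model's analytically
known intersection geometry to ~10⁻⁶ Bohr.

The other examples follow the same pattern, one capability each:
single-point execution and the text dialect (`01`), numerical derivatives
vs closed forms (`02`), QM/MM embedding (`03`), the active-learning
fallback/committee/database tree (`05`), and population analysis with
confidence intervals (`06`).

A thin CLI wraps the same library calls:

```bash
esi run --tree tree.yaml --qmin QM.in --out QM.out
esi sequence --tree tree.yaml --geoms traj.xyz --requests "h grad"
esi meci --tree tree.yaml --geom start.xyz --method two-stage
esi analyze populations --traj t1.txt --traj t2.txt --nstates 3
```

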