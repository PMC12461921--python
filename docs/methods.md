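# Methods

This note documents the models, algorithms, numerical choices and open
design decisions behind `esi`, and what the test suite does and does not
demonstrate.

## State space and containers

The electronic state space is declared per spin multiplicity
(`states_per_mult[m]` states of multiplicity m+1).  Every Ms sublevel is
carried explicitly so that spin-dependent consumers (surface hopping with
spin–orbit coupling) can treat the Hamiltonian as one flat matrix; all
spin-independent data (energies, gradients, spin-free NACs, dipoles) are
duplicated across the sublevels of a multiplet.  The canonical ordering —
ascending multiplicity, then state index, then ascending Ms — is a global
convention of this package: no ordering is canonical in the field, but one
must be fixed because every tensor is indexed by it.

Internal units are Hartree atomic units everywhere (Hartree, Bohr,
e·Bohr); xyz input in Ångström is converted on read with
1 Bohr = 0.529177210903 Å (CODATA 2018).  H and S are stored complex even
for real-valued backends, which makes spin–orbit blocks and complex
overlap phases representable without case splits.  The text dialect
serializes with 15 significant digits, so a write/read round trip is
reproducible to ≤1e-12 absolute.  Energy displays in meV use
1 Eh = 27211.386245988 meV, one decimal below 20 meV and whole numbers
above (the convention that renders sub-meV seam gaps and ~20 meV committee
thresholds the way they are usually reported).

`QMout` allocates only requested tensors; attribute absence is the memory
contract and doubles as the "not computed" flag.

## Analytic model backends (the oracles)

The leaf backend is a linear-vibronic-coupling (LVC) family: a shared
harmonic potential ½(R−R₀)ᵀK(R−R₀) plus per-state shifts ε_i and linear
terms κ_i·(R−R₀) on the diagonal, and constant λ_ij plus linear μ_ij·(R−R₀)
interstate couplings.  Eigendecomposition of W(R) gives adiabatic energies;
Hellmann–Feynman yields exact gradients C_iᵀ(∂W/∂R)C_i and couplings
C_iᵀ(∂W/∂R)C_j/(E_j−E_i).  Overlaps are computed in the frozen diabatic
basis, S = C(R_a)ᵀC(R_b), which is exact for this model family and mirrors
what a wave-function-overlap code provides for ab initio wave functions.
Eigenvector phases are fixed deterministically (largest-magnitude component
positive); a seeded option flips overlap-column signs at random to emulate
the arbitrary phases of independently converged wave functions.

Adiabatic gradients/NACs are declared undefined below a 1e-8 Hartree gap
(degeneracy error rather than a numerically exploding vector); tests near
intersections use the diabatic differentiation path instead.

Three deliberate fixture extensions, all documented as such:

* **Gaussian diagonal bumps** A·exp(−|R−c|²/2w²) plant localized
  disagreement between two otherwise identical models (committee tests).
* **Stark embedding**: with point charges present, each diagonal diabatic
  energy gains Σ_q q·d_i·(c−r_q)/|c−r_q|³, with d_i a per-state dipole
  vector and c the current centroid of the QM atoms.  This gives QM/MM
  electrostatic embedding an analytic, fully differentiable oracle (in both
  QM-atom and charge positions).  It is a model of a state-specific
  environment response, not a multipole expansion of anything.
* **Planted intersections**: with K = k·I, a diagonal gap varying only
  along coordinate 0 and a coupling varying only along coordinate 1, the
  seam is {x₀ = −Δε/a, x₁ = 0} and the seam minimum of the mean energy is
  closed-form — MECI recovery becomes an exact parameter-recovery test.

The toy MM backend is harmonic bonds plus Coulomb between fixed partial
charges; it exists to exercise the QM/MM call tree, not to model matter.

## Lifecycle, saves, trees

Initialization (molecule → template → resources → finalize) happens once;
per-step work is set_coords/set_requests/run/get_qmout.  Requests are
validated against the interface's declared feature set; hybrid parents
derive their set from their children's (e.g. the differentiation hybrid
adds `grad`/`nacdr` on top of a child providing `h`/`overlap`) and refuse
irreconcilable trees at finalize time with the missing capability named.

The save registry keys every payload by (step, label), tracks the last
successful step, and classifies incoming steps as new/repeated/restart/
inconsistent.  `inconsistent` is returned, not raised — what to do about a
step jump is the caller's policy, deliberately left to the driver.
Retention defaults to current + previous step; entries flagged persistent
survive garbage collection.  Fast interfaces hold the registry in memory
and flush to `SAVE/<step>/<label>` (+ a `SAVE/STEP` file) only on demand;
pointing `resources["savedir"]` at a flushed directory reloads it and
flags the restart.

Child errors propagate as exceptions wrapped with the name path through
the tree (`fallback/trial/leader`), preserving the original exception.
Child execution is sequential in-process; the contract is that results are
keyed by child name and independent of completion order, so a parallel
queue could be substituted without observable change.  The ab initio base
class (subprocess scheduling for external quantum-chemistry programs) is a
stub fixing the inheritance layout and the scheduling contract only.

## Numerical differentiation

Central differences over 6·N_atom displaced child runs (one child per
coordinate, reused for ±; the call count, not the object count, is the
contract).  Default δ = 0.01 Bohr: large enough that Eh-scale energies
differenced at 1e-15 relative precision retain ~1e-11 accuracy, small
enough that O(δ²) truncation stays below typical gradient scales; the
tests mostly use 1e-3–1e-4 where the oracles make truncation visible.

All displaced overlaps are anchored at the reference wave function
(injected into each displaced child's save registry), never chained
between displacements.  Overlap columns are sign-fixed so the diagonal is
non-negative before use; a diagonal magnitude below 0.5 attaches a
state-tracking warning to the result metadata.  With phase fixing on, all
assembled tensors are invariant under arbitrary per-column sign flips of
child overlaps (verified exactly in the tests).

The diabatized transform S†HS is explicitly re-Hermitized before elements
are extracted, suppressing asymmetric floating-point noise.  In the
diabatic NAC formula the division by ΔE_ij is refused below 1e-6 Hartree:
affected elements are returned as zero and flagged in
`metadata["nacdr_flagged"]` rather than emitted as huge numbers.

One subtlety: for the Hamiltonian-based formulas the conjugation S†HS
(with S_ij = ⟨Ψ_i(ref)|Ψ_j(disp)⟩) produces derivative couplings with the
same sign convention as the overlap-difference formula — both were checked
against the analytic NAC oracle.  For property matrices (SOC, dipoles) the
correct diabatization is the opposite conjugation S·M·S†, which expresses
the displaced matrix in the reference basis; with S†MS a linear-dipole
model does not recover its own slope.  The package uses each where it is
correct.  Note the two routes differentiate different objects: the
adiabatic scheme approximates the derivative of the adiabatic matrix
(including eigenvector-rotation terms), the diabatic scheme the derivative
with rotations transformed away.

Analytic pass-through mixing (using child analytic gradients where
available and differentiating only the rest) is out of scope in this
version, though feature negotiation exposes the needed information.

## QM/MM

Subtractive (ONIOM-like) with electrostatic embedding, following the
MML/MMS topology: H_total = H_QM + (E_MML − E_MMS)·I.  Embedding charges
are the full-system MM charge list restricted to the MM atoms; the
small-region MM child runs charge-free, so QM-region internal
electrostatics appear once classically (in MML) alongside the QM
treatment — a documented convention choice, made so that no charge–charge
term is subtracted that the QM child never added.  Gradients:
QM rows g_QM + g_MML[qm] − g_MMS, MM rows g_MML[mm] plus the QM child's
point-charge forces mapped back; by construction the assembled gradient is
the exact derivative of the assembled energy, which the tests verify by
finite differences.  NACs pass through on QM atoms and are zero on MM
atoms (a state-independent environment).  No link atoms: a bond crossing
the region boundary is rejected with instructions to choose complete
molecules.  Polarizable embedding and periodic boundaries are out of
scope.

## Workflow hybrids

The committee compares only configured attributes (default: Hamiltonian
diagonal, MAE metric, threshold 0.8 mEh = 22 meV — the scale at which two
independently trained ML potentials are considered to disagree).  Any
advisor exceeding any threshold raises a dedicated deviation exception, so
a fallback parent can distinguish "models disagree" from "child crashed";
both trigger the backup, whose result is trusted unconditionally (checking
the backup against a threshold too would need a second reference — out of
scope).  The failure counter counts consecutive trial failures and resets
on success; reaching the limit (default 2) raises a termination signal
distinct from an error, which the sequence harness converts into a stop
reason with partial results.

The database interface records geometry + all populated tensors + step +
timestamp as JSON-lines (arrays as nested lists, complex as re/im) before
passing results through unchanged; a storage failure raises *before*
pass-through so training data is never lost silently.  The schema maps
one-to-one onto atomic-simulation-database rows; the mapping is
documentation, not a dependency.

## MECI optimizers

Penalty method: minimize F = (E_i+E_j)/2 + σΔE²/(ΔE+α) with
w_i = ½ + σ(ΔE² + 2αΔE)/(ΔE+α)², w_j = 1−w_i as the chain-rule weights;
BFGS with Armijo backtracking (the objective history is monotone), max 200
iterations, gradient tolerance 1e-6, step tolerance 1e-5 Bohr.  Defaults
σ = 3.5, α = 0.02 Hartree.  A residual gap remains by construction,
shrinking with growing σ (a property the tests check).

Projected-gradient method: the branching plane is spanned by the
normalized gradient difference b₁ and the NAC vector orthonormalized
against it (b₂); normalizing the NAC makes the construction insensitive to
its 1/ΔE growth near the seam.  Each iteration (i) takes first-order
Newton steps along b₁ to close the gap, targeting gap_tol/2 rather than
zero — backends legitimately refuse analytic derivatives at numerically
exact degeneracy — and (ii) takes a backtracking descent step along the
mean-energy gradient with both branching-plane directions projected out.
Convergence: gap ≤ 1e-6 Hartree and projected gradient ≤ 1e-6.  When the
NAC is flagged undefined (gap under the division threshold), the last
well-defined b₂ is reused after re-orthogonalization; if none exists the
optimizer asks the caller to start farther from the seam.  Whether phase
fixing is applied to the overlaps feeding the diabatic NAC is a child-side
toggle; both settings give identical results on the models (phase
invariance is exact), so the default is on.

Both optimizers talk to interfaces only through requests, so the projected
method runs unchanged over the differentiation hybrid wrapping an
energies+overlaps-only child — the configuration the recovery tests use.

## What the synthetic conditions do and do not show

All quantitative tests run on LVC-family models.  These have exact
overlaps, noiseless energies, quadratic-plus-conical topology and cheap
evaluations; real electronic structure adds SCF/CI noise, state-tracking
failures, non-quadratic seams and cost.  Passing tests therefore
demonstrate the *interface machinery* — contracts, assembly formulas,
counting, phase handling, convergence orders, control flow — at the
stated tolerances, not the accuracy of any electronic-structure method.
Problem sizes (2-atom models, 100 random models, 20 planted intersections,
100-step workflow sequences) were chosen as the smallest sizes at which
every claimed property is exercised with margin.
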