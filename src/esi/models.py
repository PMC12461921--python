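"""Analytic diabatic model potentials and a toy MM force field.

These are "fast" leaf backends in the linear-vibronic-coupling family: a
shared harmonic ground potential plus per-state energy shifts and linear
terms, with constant and linear interstate couplings,

    W_ii(R) = 1/2 (R-R0)^T K (R-R0) + eps_i + kappa_i . (R-R0) [+ bumps]
    W_ij(R) = lambda_ij + mu_ij . (R-R0)            (i != j)

Adiabatic energies/gradients/couplings follow in closed form from the
eigendecomposition of W, and wave-function overlaps between two geometries
are exact in the frozen diabatic basis, S = C(R_a)^T C(R_b) -- the same
quantity an overlap code provides for ab initio wave functions.  That makes
these models exhaustive oracles for every hybrid interface in the package
(numerical differentiation, QM/MM, committees, optimizers).

Optional extras turn the models into richer fixtures: Gaussian diagonal
"bumps" (to plant localized disagreement between two committee members),
per-state Stark dipoles (an analytic electrostatic-embedding response to
point charges), a constant spin-orbit block, and seeded random phase flips
on overlap columns (to exercise consumer-side phase correction).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from .containers import Coordinates, FeatureSet, MoleculeSpec, QMout, allocate_qmout
from .base import FastInterface, register_interface
from .errors import DegeneracyError, InvalidMoleculeError, MappingError
from .states import model_state_index

__all__ = [
    "DiabaticModel",
    "MMModel",
    "eval_adiabatic",
    "analytic_gradient",
    "analytic_nac",
    "overlaps",
    "mm_evaluate",
    "load_diabatic_model",
    "load_mm_model",
    "random_model",
    "planted_ci_model",
    "with_bump",
    "model_molecule",
    "LVCModelInterface",
    "MMInterface",
    "DEGENERACY_THRESHOLD",
]

#: Gap below which analytic adiabatic gradients/NACs are declared undefined.
DEGENERACY_THRESHOLD = 1e-8


# ---------------------------------------------------------------------------
# Diabatic model
# ---------------------------------------------------------------------------

@dataclass
class DiabaticModel:
    """Multi-state diabatic vibronic model on ``n_dof`` Cartesian coordinates."""

    r0: np.ndarray                    # (ndof,) reference geometry, Bohr
    k: np.ndarray                     # (ndof, ndof) PSD force-constant matrix
    epsilon: np.ndarray               # (n,) diabatic energy shifts, Hartree
    kappa: np.ndarray                 # (n, ndof) per-state linear terms
    lam: np.ndarray | None = None     # (n, n) constant couplings, sym, zero diag
    mu: np.ndarray | None = None      # (n, n, ndof) linear couplings, sym
    dip0: np.ndarray | None = None    # (3, n, n) constant diabatic dipole matrices
    dip1: np.ndarray | None = None    # (3, n, n, ndof) linear dipole slopes
    soc: np.ndarray | None = None     # (n, n) constant SOC block (complex)
    stark: np.ndarray | None = None   # (n, 3) per-state Stark dipole vectors
    bumps: list = field(default_factory=list)  # [(amp (n,), center (ndof,), width)]

    def __post_init__(self):
        self.r0 = np.asarray(self.r0, float).ravel()
        n_dof = len(self.r0)
        k = np.asarray(self.k, float)
        if k.ndim == 0:
            k = np.eye(n_dof) * float(k)
        elif k.ndim == 1:
            k = np.diag(k)
        self.k = k
        self.epsilon = np.asarray(self.epsilon, float).ravel()
        n = len(self.epsilon)
        self.kappa = np.asarray(self.kappa, float).reshape(n, n_dof)
        self.lam = (
            np.zeros((n, n)) if self.lam is None else np.asarray(self.lam, float)
        )
        self.mu = (
            np.zeros((n, n, n_dof)) if self.mu is None else np.asarray(self.mu, float)
        )
        if not np.allclose(self.lam, self.lam.T):
            raise InvalidMoleculeError("lambda coupling matrix must be symmetric")
        if not np.allclose(self.mu, np.swapaxes(self.mu, 0, 1)):
            raise InvalidMoleculeError("mu coupling tensor must be symmetric")
        if self.dip0 is not None:
            self.dip0 = np.asarray(self.dip0, float).reshape(3, n, n)
        if self.dip1 is not None:
            self.dip1 = np.asarray(self.dip1, float).reshape(3, n, n, n_dof)
        if self.soc is not None:
            self.soc = np.asarray(self.soc, complex).reshape(n, n)
        if self.stark is not None:
            self.stark = np.asarray(self.stark, float).reshape(n, 3)
        self.bumps = [
            (np.asarray(a, float).ravel(), np.asarray(c, float).ravel(), float(w))
            for a, c, w in self.bumps
        ]

    @property
    def n_states(self) -> int:
        return len(self.epsilon)

    @property
    def n_dof(self) -> int:
        return len(self.r0)

    # -- diabatic matrix and its exact derivatives -----------------------
    def diabatic(self, R) -> np.ndarray:
        """Diabatic potential matrix W(R), symmetric, Hartree."""
        dx = np.asarray(R, float).ravel() - self.r0
        n = self.n_states
        v0 = 0.5 * dx @ self.k @ dx
        w = np.full((n, n), 0.0)
        np.fill_diagonal(w, v0 + self.epsilon + self.kappa @ dx)
        w = w + self.lam + self.mu @ dx
        for amp, center, width in self.bumps:
            g = np.exp(-0.5 * np.sum((np.asarray(R, float).ravel() - center) ** 2) / width**2)
            w[np.diag_indices(n)] += amp * g
        return w

    def diabatic_gradient(self, R) -> np.ndarray:
        """dW/dR, shape (n, n, ndof)."""
        x = np.asarray(R, float).ravel()
        dx = x - self.r0
        n, nd = self.n_states, self.n_dof
        dw = np.array(self.mu)  # linear couplings
        kdx = self.k @ dx
        for i in range(n):
            dw[i, i] += kdx + self.kappa[i]
        for amp, center, width in self.bumps:
            d = x - center
            g = np.exp(-0.5 * np.sum(d**2) / width**2)
            for i in range(n):
                dw[i, i] += amp[i] * g * (-d / width**2)
        return dw

    # -- point-charge (Stark) embedding ---------------------------------
    def stark_shifts(self, R, pc_pos, pc_val) -> np.ndarray:
        """Per-state diagonal shift from point charges: sum_q q d_i.(c-r_q)/|c-r_q|^3."""
        if self.stark is None:
            return np.zeros(self.n_states)
        c = np.asarray(R, float).reshape(-1, 3).mean(axis=0)
        v = c[None, :] - np.asarray(pc_pos, float)          # (npc, 3)
        r3 = np.sum(v**2, axis=1) ** 1.5
        field = np.sum(np.asarray(pc_val, float)[:, None] * v / r3[:, None], axis=0)
        return self.stark @ field

    def stark_gradients(self, R, pc_pos, pc_val):
        """Exact derivatives of the Stark shifts.

        Returns (d_shift/dR with shape (n, ndof), d_shift/d(pc positions)
        with shape (n, npc, 3)).
        """
        n = self.n_states
        nat = self.n_dof // 3
        pc_pos = np.asarray(pc_pos, float)
        pc_val = np.asarray(pc_val, float)
        npc = len(pc_val)
        if self.stark is None:
            return np.zeros((n, self.n_dof)), np.zeros((n, npc, 3))
        c = np.asarray(R, float).reshape(-1, 3).mean(axis=0)
        d_dc = np.zeros((n, 3))
        d_dpc = np.zeros((n, npc, 3))
        for q in range(npc):
            v = c - pc_pos[q]
            r2 = v @ v
            r3, r5 = r2**1.5, r2**2.5
            for i in range(n):
                di = self.stark[i]
                jac = di / r3 - 3.0 * (di @ v) * v / r5  # d/dc of d_i.v/|v|^3
                d_dc[i] += pc_val[q] * jac
                d_dpc[i, q] = -pc_val[q] * jac
        # the centroid depends equally on every atom
        d_dR = np.tile(d_dc[:, None, :] / nat, (1, nat, 1)).reshape(n, self.n_dof)
        return d_dR, d_dpc

    def effective_diabatic(self, R, pc_pos=None, pc_val=None) -> np.ndarray:
        w = self.diabatic(R)
        if pc_pos is not None and len(np.atleast_1d(pc_val)) > 0:
            w[np.diag_indices(self.n_states)] += self.stark_shifts(R, pc_pos, pc_val)
        return w

    def dipole(self, R) -> np.ndarray:
        """Diabatic dipole matrices (3, n, n) at R (zero if unparametrized)."""
        n = self.n_states
        d = np.zeros((3, n, n)) if self.dip0 is None else np.array(self.dip0)
        if self.dip1 is not None:
            dx = np.asarray(R, float).ravel() - self.r0
            d = d + self.dip1 @ dx
        return d

    def copy(self) -> "DiabaticModel":
        return copy.deepcopy(self)


def _fix_phases(C: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector phases: largest-|component| made positive."""
    C = np.array(C)
    for j in range(C.shape[1]):
        k = int(np.argmax(np.abs(C[:, j])))
        if C[k, j] < 0:
            C[:, j] = -C[:, j]
    return C


def eval_adiabatic(model: DiabaticModel, R, pc_pos=None, pc_val=None):
    """Adiabatic energies (ascending) and phase-fixed eigenvector columns."""
    w = model.effective_diabatic(R, pc_pos, pc_val)
    e, c = np.linalg.eigh(w)
    return e, _fix_phases(c)


def _check_gap(e: np.ndarray, i: int, what: str) -> None:
    for j in range(len(e)):
        if j != i and abs(e[i] - e[j]) < DEGENERACY_THRESHOLD:
            raise DegeneracyError(
                f"{what} undefined: states {i} and {j} degenerate "
                f"(gap {abs(e[i]-e[j]):.2e} Hartree)"
            )


def analytic_gradient(model: DiabaticModel, R, i: int, pc_pos=None, pc_val=None):
    """Exact Hellmann-Feynman gradient of adiabatic state ``i`` (0-based)."""
    e, c = eval_adiabatic(model, R, pc_pos, pc_val)
    _check_gap(e, i, "gradient")
    dw = model.diabatic_gradient(R)
    grad = np.einsum("a,abd,b->d", c[:, i], dw, c[:, i])
    if pc_pos is not None and len(np.atleast_1d(pc_val)) > 0:
        d_dR, _ = model.stark_gradients(R, pc_pos, pc_val)
        grad = grad + (c[:, i] ** 2) @ d_dR
    return grad


def pointcharge_gradient(model: DiabaticModel, R, i: int, pc_pos, pc_val):
    """Exact gradient of adiabatic state ``i`` w.r.t. point-charge positions."""
    e, c = eval_adiabatic(model, R, pc_pos, pc_val)
    _check_gap(e, i, "point-charge gradient")
    _, d_dpc = model.stark_gradients(R, pc_pos, pc_val)
    return np.einsum("a,aqd->qd", c[:, i] ** 2, d_dpc)


def analytic_nac(model: DiabaticModel, R, i: int, j: int, pc_pos=None, pc_val=None):
    """Exact nonadiabatic coupling vector <Psi_i|dPsi_j/dR> (0-based states).

    Antisymmetric under i<->j; undefined (DegeneracyError) below the
    degeneracy threshold.
    """
    if i == j:
        return np.zeros(model.n_dof)
    e, c = eval_adiabatic(model, R, pc_pos, pc_val)
    if abs(e[j] - e[i]) < DEGENERACY_THRESHOLD:
        raise DegeneracyError(
            f"NAC undefined: states {i},{j} gap {abs(e[j]-e[i]):.2e} Hartree"
        )
    dw = model.diabatic_gradient(R)
    coup = np.einsum("a,abd,b->d", c[:, i], dw, c[:, j])
    if pc_pos is not None and len(np.atleast_1d(pc_val)) > 0:
        d_dR, _ = model.stark_gradients(R, pc_pos, pc_val)
        coup = coup + np.einsum("a,ad->d", c[:, i] * c[:, j], d_dR)
    return coup / (e[j] - e[i])


def overlaps(model: DiabaticModel, R_a, R_b, pc_a=None, pc_b=None) -> np.ndarray:
    """Wave-function overlap matrix S_ij = <Psi_i(R_a)|Psi_j(R_b)>.

    Exact in the frozen diabatic basis: S = C(R_a)^T C(R_b); orthogonal,
    and the identity when R_b == R_a.
    """
    _, ca = eval_adiabatic(model, R_a, *(pc_a or (None, None)))
    _, cb = eval_adiabatic(model, R_b, *(pc_b or (None, None)))
    return ca.T @ cb


# ---------------------------------------------------------------------------
# Toy MM force field
# ---------------------------------------------------------------------------

@dataclass
class MMModel:
    """Harmonic bonds + Coulomb interaction among fixed partial charges."""

    n_atoms: int
    bonds: list          # [(i, j, k_force, r0), ...]
    charges: np.ndarray  # (n_atoms,), elementary charge
    coulomb: bool = True

    def __post_init__(self):
        self.charges = np.asarray(self.charges, float).ravel()
        if len(self.charges) != self.n_atoms:
            raise InvalidMoleculeError("one partial charge per MM atom required")
        self.bonds = [(int(i), int(j), float(k), float(r0)) for i, j, k, r0 in self.bonds]

    def evaluate(self, R):
        """Energy (Hartree) and gradient (n_atoms, 3) at R (Bohr)."""
        R = np.asarray(R, float).reshape(self.n_atoms, 3)
        e = 0.0
        g = np.zeros_like(R)
        for i, j, k, r0 in self.bonds:
            d = R[i] - R[j]
            r = np.linalg.norm(d)
            e += 0.5 * k * (r - r0) ** 2
            f = k * (r - r0) * d / r
            g[i] += f
            g[j] -= f
        if self.coulomb:
            for p in range(self.n_atoms):
                for q in range(p + 1, self.n_atoms):
                    qq = self.charges[p] * self.charges[q]
                    if qq == 0.0:
                        continue
                    d = R[p] - R[q]
                    r = np.linalg.norm(d)
                    e += qq / r
                    f = -qq * d / r**3
                    g[p] += f
                    g[q] -= f
        return e, g

    def restrict(self, atoms) -> "MMModel":
        """Sub-model over ``atoms``; bonds crossing the boundary are an error."""
        atoms = list(atoms)
        inside = set(atoms)
        remap = {a: k for k, a in enumerate(atoms)}
        bonds = []
        for i, j, k, r0 in self.bonds:
            if (i in inside) != (j in inside):
                raise MappingError(
                    f"bond {i}-{j} crosses the QM/MM boundary; link atoms are "
                    "not supported, choose a region of complete molecules"
                )
            if i in inside:
                bonds.append((remap[i], remap[j], k, r0))
        return MMModel(len(atoms), bonds, self.charges[atoms], self.coulomb)


def mm_evaluate(mmmodel: MMModel, R):
    """(energy, gradient, charges) of the MM model at R."""
    e, g = mmmodel.evaluate(R)
    return e, g, mmmodel.charges.copy()


# ---------------------------------------------------------------------------
# Parameter files (YAML)
# ---------------------------------------------------------------------------

def load_diabatic_model(source) -> DiabaticModel:
    """Build a DiabaticModel from a mapping or a YAML parameter file."""
    if isinstance(source, DiabaticModel):
        return source
    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    kw = {k: source[k] for k in (
        "r0", "k", "epsilon", "kappa", "lam", "mu", "dip0", "dip1", "soc",
        "stark", "bumps",
    ) if k in source and source[k] is not None}
    if "soc" in kw:
        kw["soc"] = np.asarray(kw["soc"], float).astype(complex)
    if "bumps" in kw:
        kw["bumps"] = [(b["amp"], b["center"], b["width"]) for b in kw["bumps"]]
    return DiabaticModel(**kw)


def load_mm_model(source) -> MMModel:
    if isinstance(source, MMModel):
        return source
    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    return MMModel(
        int(source["n_atoms"]),
        [tuple(b) for b in source["bonds"]],
        source["charges"],
        bool(source.get("coulomb", True)),
    )


# ---------------------------------------------------------------------------
# Seeded fixture factories
# ---------------------------------------------------------------------------

def random_model(
    rng: np.random.Generator,
    n_states: int = 2,
    n_atoms: int = 2,
    spacing: float = 0.3,
    coupling: float = 0.05,
    with_dipoles: bool = True,
) -> DiabaticModel:
    """Random well-separated diabatic model (gaps of order ``spacing``)."""
    nd = 3 * n_atoms
    r0 = rng.normal(0.0, 0.5, nd)
    kdiag = rng.uniform(0.3, 1.0, nd)
    eps = spacing * np.arange(n_states) + rng.uniform(0.0, 0.3 * spacing, n_states)
    kappa = rng.normal(0.0, 0.05, (n_states, nd))
    lam = rng.normal(0.0, coupling, (n_states, n_states))
    lam = 0.5 * (lam + lam.T)
    np.fill_diagonal(lam, 0.0)
    mu = rng.normal(0.0, coupling, (n_states, n_states, nd))
    mu = 0.5 * (mu + np.swapaxes(mu, 0, 1))
    for i in range(n_states):
        mu[i, i] = 0.0
    dip0 = dip1 = None
    if with_dipoles:
        dip0 = rng.normal(0.0, 0.5, (3, n_states, n_states))
        dip0 = 0.5 * (dip0 + np.swapaxes(dip0, 1, 2))
        dip1 = rng.normal(0.0, 0.1, (3, n_states, n_states, nd))
        dip1 = 0.5 * (dip1 + np.swapaxes(dip1, 1, 2))
    return DiabaticModel(r0, kdiag, eps, kappa, lam, mu, dip0=dip0, dip1=dip1)


def planted_ci_model(
    rng: np.random.Generator,
    n_atoms: int = 2,
    n_states: int = 2,
    gap_slope: tuple[float, float] = (0.1, 0.4),
    coupling_slope: tuple[float, float] = (0.05, 0.2),
):
    """Model with an analytically known minimum-energy conical intersection.

    The two intersecting states differ linearly along coordinate 0 and are
    coupled linearly along coordinate 1 (K = k*I), so the seam is
    {x0 = -d_eps/a, x1 = 0} and the mean energy is minimized on the seam at
    x_j = -kbar_j/k for the remaining coordinates.  For ``n_states == 3`` a
    well-separated lower state is added below the intersecting pair.

    Returns ``(model, meci_geometry, (i_lower, i_upper))`` with the MECI
    geometry as an (n_atoms, 3) array and 0-based adiabatic state indices.
    """
    nd = 3 * n_atoms
    r0 = rng.normal(0.0, 0.3, nd)
    kd = rng.uniform(0.4, 0.9)
    a = rng.uniform(*gap_slope) * rng.choice([-1.0, 1.0])
    b = rng.uniform(*coupling_slope) * rng.choice([-1.0, 1.0])
    deps = rng.uniform(0.05, 0.15)
    kbar = np.zeros(nd)
    kbar[2:] = rng.normal(0.0, 0.05, nd - 2)

    if n_states == 2:
        eps = np.array([0.0, deps])
        pair = (0, 1)
    elif n_states == 3:
        eps = np.array([-0.6, 0.0, deps])
        pair = (1, 2)
    else:
        raise ValueError("planted_ci_model supports 2 or 3 states")
    n = n_states
    kappa = np.tile(kbar, (n, 1))
    i_lo, i_up = pair
    kappa[i_lo, 0] = kbar[0] - 0.5 * a
    kappa[i_up, 0] = kbar[0] + 0.5 * a
    if n == 3:
        kappa[0] = rng.normal(0.0, 0.03, nd)  # spectator state, decoupled
    mu = np.zeros((n, n, nd))
    mu[i_lo, i_up, 1] = mu[i_up, i_lo, 1] = b
    model = DiabaticModel(r0, kd, eps, kappa, lam=None, mu=mu)

    x_meci = np.zeros(nd)
    x_meci[0] = -deps / a
    x_meci[1] = 0.0
    x_meci[2:] = -kbar[2:] / kd
    meci = (model.r0 + x_meci).reshape(n_atoms, 3)
    return model, meci, pair


def with_bump(model: DiabaticModel, amp, center, width: float) -> DiabaticModel:
    """Copy of ``model`` with an extra Gaussian diagonal bump (committee fixture)."""
    out = model.copy()
    amp = np.broadcast_to(np.atleast_1d(np.asarray(amp, float)), (model.n_states,))
    out.bumps = list(out.bumps) + [
        (np.array(amp), np.asarray(center, float).ravel(), float(width))
    ]
    return out


def model_molecule(model: DiabaticModel, states_per_mult=None, n_point_charges=0) -> MoleculeSpec:
    """Dummy MoleculeSpec matching a model's degrees of freedom.

    By default all model states are treated as singlets.
    """
    if model.n_dof % 3:
        raise InvalidMoleculeError("model n_dof must be 3*n_atoms for interface use")
    nat = model.n_dof // 3
    spm = states_per_mult if states_per_mult is not None else [model.n_states]
    return MoleculeSpec(["X"] * nat, spm, n_point_charges=n_point_charges)


# ---------------------------------------------------------------------------
# Interfaces
# ---------------------------------------------------------------------------

@register_interface
class LVCModelInterface(FastInterface):
    """Fast interface over a :class:`DiabaticModel`.

    Template keys: ``paramfile`` (YAML model parameters) or ``model_object``
    (a DiabaticModel passed programmatically), optional ``features`` (mask
    restricting the advertised capability set, e.g. ``h overlap`` to emulate
    a backend without analytic derivatives) and ``overlap_phase_flip_seed``
    (adversarial random overlap-column signs).

    Overlaps are computed against the wave function stored in the save
    registry: by default the previous step's, or the step/label named by the
    ``control`` entries ``overlap_anchor_step``/``overlap_anchor_label`` (a
    parent doing displaced-geometry overlaps anchors them all at its
    reference geometry this way).
    """

    interface_id = "lvc_model"

    FULL_FEATURES = FeatureSet(
        {
            "h", "grad", "overlap", "nacdr", "dm",
            "grad_pc", "nacdr_pc",
            "accepts_point_charges",
        }
    )

    def __init__(self, name=None):
        super().__init__(name)
        self.model: DiabaticModel | None = None
        self.n_overlap_calls = 0
        self._phase_rng: np.random.Generator | None = None

    def _features(self) -> FeatureSet:
        mask = self.qmin.template.get("features")
        feats = self.FULL_FEATURES
        if mask:
            if isinstance(mask, str):
                mask = mask.split()
            feats = FeatureSet(set(mask) & set(self.FULL_FEATURES))
        return feats

    def _finalize(self) -> None:
        tpl = self.qmin.template
        if "model_object" in tpl:
            self.model = load_diabatic_model(tpl["model_object"])
        elif "paramfile" in tpl:
            self.model = load_diabatic_model(tpl["paramfile"])
        else:
            raise InvalidMoleculeError(
                f"{self.name}: template must provide 'paramfile' or 'model_object'"
            )
        mol = self.qmin.molecule
        n_model = sum(mol.states_per_mult)
        if self.model.n_states != n_model:
            raise InvalidMoleculeError(
                f"model has {self.model.n_states} states but molecule declares "
                f"{n_model} spin-free states"
            )
        if self.model.n_dof != 3 * mol.n_atoms:
            raise InvalidMoleculeError(
                f"model n_dof {self.model.n_dof} != 3*n_atoms {3 * mol.n_atoms}"
            )
        seed = tpl.get("overlap_phase_flip_seed")
        if seed is not None:
            self._phase_rng = np.random.default_rng(int(seed))

    # -- helpers ---------------------------------------------------------
    def _pc(self):
        c = self.qmin.coords
        if c.point_charge_positions is not None and len(c.point_charge_values):
            return c.point_charge_positions, c.point_charge_values
        return None, None

    def _execute(self) -> QMout:
        mol = self.qmin.molecule
        req = self.qmin.requests
        q = allocate_qmout(mol, req)
        R = self.qmin.coords.positions.ravel()
        pc_pos, pc_val = self._pc()
        e, c = eval_adiabatic(self.model, R, pc_pos, pc_val)
        smap = mol.state_map
        midx = model_state_index(mol.states_per_mult)
        n_total = mol.n_total

        if req.hamiltonian:
            for p in range(n_total):
                q.h[p, p] = e[midx[p]]
            if self.model.soc is not None:
                for p in range(n_total):
                    for r in range(n_total):
                        if smap[p].mult != smap[r].mult:
                            q.h[p, r] += self.model.soc[midx[p], midx[r]]
        if req.gradients:
            for p in req.gradient_states(n_total):
                g = analytic_gradient(self.model, R, midx[p - 1], pc_pos, pc_val)
                q.grad[p - 1] = g.reshape(mol.n_atoms, 3)
        if req.nac_vectors:
            nac_model = {}
            for i in range(self.model.n_states):
                for j in range(self.model.n_states):
                    if i != j:
                        nac_model[i, j] = analytic_nac(
                            self.model, R, i, j, pc_pos, pc_val
                        )
            for p in range(n_total):
                for r in range(n_total):
                    sp, sr = smap[p], smap[r]
                    if p != r and sp.mult == sr.mult and sp.ms == sr.ms:
                        q.nacdr[p, r] = nac_model[midx[p], midx[r]].reshape(
                            mol.n_atoms, 3
                        )
        if req.overlaps:
            q.s[:] = self._compute_overlaps(c, smap, midx, n_total)
        if req.dipoles:
            d_dia = self.model.dipole(R)
            d_ad = np.einsum("ai,pab,bj->pij", c, d_dia, c)
            for p in range(n_total):
                for r in range(n_total):
                    sp, sr = smap[p], smap[r]
                    if sp.mult == sr.mult and sp.ms == sr.ms:
                        q.dm[:, p, r] = d_ad[:, midx[p], midx[r]]
        if req.point_charge_derivatives and pc_pos is not None:
            for p in range(n_total):
                q.grad_pc[p] = pointcharge_gradient(
                    self.model, R, midx[p], pc_pos, pc_val
                )
        # persistence: this step's wave function, for next-step overlaps
        step = req.step
        self.save.put(step, "wavefunction", c.copy())
        self.save.put(step, "energies", e.copy())
        self.save.garbage_collect(step)
        return q

    def _compute_overlaps(self, c_now, smap, midx, n_total) -> np.ndarray:
        self.n_overlap_calls += 1
        ctrl = self.qmin.control
        step = self.qmin.requests.step
        anchor_step = ctrl.get("overlap_anchor_step", step - 1)
        anchor_label = ctrl.get("overlap_anchor_label", "wavefunction")
        c_ref = self.save.get(anchor_step, anchor_label)
        s_model = np.asarray(c_ref).T @ c_now
        if self._phase_rng is not None:
            flips = self._phase_rng.choice([-1.0, 1.0], size=s_model.shape[1])
            s_model = s_model * flips[None, :]
        s = np.zeros((n_total, n_total), complex)
        for p in range(n_total):
            for r in range(n_total):
                sp, sr = smap[p], smap[r]
                if sp.mult == sr.mult and sp.ms == sr.ms:
                    s[p, r] = s_model[midx[p], midx[r]]
        return s


@register_interface
class MMInterface(FastInterface):
    """Fast interface over an :class:`MMModel` (single electronic state).

    Always returns its fixed partial-charge list alongside energy/gradient
    (``returns_point_charges`` mode), as a QM/MM parent requires.
    """

    interface_id = "mm_model"

    def __init__(self, name=None):
        super().__init__(name)
        self.model: MMModel | None = None

    def _features(self) -> FeatureSet:
        return FeatureSet({"h", "grad", "returns_point_charges"})

    def _finalize(self) -> None:
        tpl = self.qmin.template
        if "model_object" in tpl:
            self.model = load_mm_model(tpl["model_object"])
        elif "paramfile" in tpl:
            self.model = load_mm_model(tpl["paramfile"])
        else:
            raise InvalidMoleculeError(
                f"{self.name}: template must provide 'paramfile' or 'model_object'"
            )
        if self.model.n_atoms != self.qmin.molecule.n_atoms:
            raise InvalidMoleculeError(
                f"MM model covers {self.model.n_atoms} atoms, molecule has "
                f"{self.qmin.molecule.n_atoms}"
            )

    def _execute(self) -> QMout:
        mol = self.qmin.molecule
        req = self.qmin.requests
        q = allocate_qmout(mol, req)
        e, g, charges = mm_evaluate(self.model, self.qmin.coords.positions)
        if req.hamiltonian:
            q.h[np.diag_indices(mol.n_total)] = e
        if req.gradients:
            for p in req.gradient_states(mol.n_total):
                q.grad[p - 1] = g
        q.atom_charges = charges
        self.save.put(req.step, "mm_energy", e)
        self.save.garbage_collect(req.step)
        return q
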