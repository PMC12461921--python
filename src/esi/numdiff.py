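"""Overlap-based numerical differentiation as a hybrid interface.

A reference child is run at the current geometry and one displaced child
per Cartesian coordinate is run at R +/- delta*e_ad.  From the resulting
adiabatic Hamiltonians H(+/-) and reference-anchored overlap matrices
S(R, R +/- delta*e_ad), derivatives are assembled either

* adiabatically (direct central differences of adiabatic quantities):

      dE_i/dR_ad       = (H_ii(+) - H_ii(-)) / (2 delta)
      <Psi_i|dPsi_j/dR> = (S_ij(+) - S_ij(-)) / (2 delta)

* or diabatically, transforming displaced quantities back to the basis of
  the reference adiabatic states before differencing:

      dE_i/dR_ad       = [S(+)^H H(+) S(+) - S(-)^H H(-) S(-)]_ii / (2 delta)
      <Psi_i|dPsi_j/dR> = [S(+)^H H(+) S(+) - S(-)^H H(-) S(-)]_ij
                          / (2 delta * dE_ij)

The diabatic route is robust where the adiabatic states mix strongly
between the reference and displaced geometries (near conical
intersections); the transformed matrices are explicitly re-Hermitized to
suppress asymmetric floating-point noise.  Overlap columns are sign-fixed
against arbitrary wave-function phases before use, so all assembled
tensors are invariant under per-column phase flips of the child overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import HybridInterface, register_interface, get_interface_class
from .containers import Coordinates, FeatureSet, QMout, RequestSet, allocate_qmout
from .errors import ChildError, NegotiationError
from .models import DEGENERACY_THRESHOLD  # noqa: F401  (shared convention)

__all__ = [
    "NumDiffConfig",
    "DisplacementSet",
    "make_displacements",
    "grad_adiabatic",
    "nac_adiabatic",
    "grad_diabatic",
    "nac_diabatic",
    "matrix_derivative",
    "fix_overlap_phases",
    "NumDiffInterface",
]

#: |dE_ij| below this is treated as degenerate in the diabatic NAC formula.
NEAR_DEGENERACY_THRESHOLD = 1e-6

_DIRS = ("x", "y", "z")


@dataclass
class NumDiffConfig:
    """Displacement length (Bohr), differencing scheme and target tensors."""

    delta: float = 0.01
    scheme: str = "adiabatic"  # or "diabatic"
    properties: tuple = ("grad", "nacdr")
    phase_fix: bool = True

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.scheme not in ("adiabatic", "diabatic"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class DisplacementSet:
    """Reference geometry plus the 6*n_atoms singly displaced copies.

    ``geometries[(a, d, sign)]`` with ``d`` in 'xyz' and ``sign`` in '+-';
    iteration order is atom-ascending, x/y/z, '+' before '-'.
    """

    reference: np.ndarray
    delta: float
    geometries: dict

    def __iter__(self):
        return iter(self.geometries.items())

    def __len__(self):
        return len(self.geometries)


def make_displacements(R, delta: float) -> DisplacementSet:
    """All single-coordinate displacements R +/- delta*e_ad."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    R = np.asarray(R, float).reshape(-1, 3)
    geoms = {}
    for a in range(len(R)):
        for d in range(3):
            for sign, s in (("+", 1.0), ("-", -1.0)):
                g = R.copy()
                g[a, d] += s * delta
                geoms[(a, _DIRS[d], sign)] = g
    return DisplacementSet(R.copy(), float(delta), geoms)


# -- elementary difference formulas -----------------------------------------

def grad_adiabatic(h_plus, h_minus, delta: float) -> np.ndarray:
    """Per-state energy derivative components from displaced Hamiltonians."""
    return (np.real(np.diag(h_plus)) - np.real(np.diag(h_minus))) / (2.0 * delta)


def nac_adiabatic(s_plus, s_minus, delta: float) -> np.ndarray:
    """Per-pair derivative-coupling components from displaced overlaps."""
    return np.real(np.asarray(s_plus) - np.asarray(s_minus)) / (2.0 * delta)


def _transformed(s, h) -> np.ndarray:
    """S^H H S, explicitly re-Hermitized."""
    s = np.asarray(s)
    t = s.conj().T @ np.asarray(h) @ s
    return 0.5 * (t + t.conj().T)


def grad_diabatic(s_plus, h_plus, s_minus, h_minus, delta: float) -> np.ndarray:
    """Per-state derivative via the diabatized transform; equals the
    adiabatic formula when both overlaps are the identity."""
    t = _transformed(s_plus, h_plus) - _transformed(s_minus, h_minus)
    return np.real(np.diag(t)) / (2.0 * delta)


def nac_diabatic(
    s_plus, h_plus, s_minus, h_minus, delta: float, gaps,
    threshold: float = NEAR_DEGENERACY_THRESHOLD,
):
    """Per-pair derivative couplings via the diabatized transform.

    ``gaps[i, j]`` is the adiabatic gap E_i - E_j at the reference geometry.
    Pairs with |gap| below ``threshold`` are undefined: their entries are
    returned as zero and their indices collected in the flagged list (never
    silently divided through).
    """
    t = _transformed(s_plus, h_plus) - _transformed(s_minus, h_minus)
    gaps = np.asarray(gaps, float)
    n = t.shape[0]
    out = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if abs(gaps[i, j]) < threshold:
                flagged.append((i, j))
            else:
                out[i, j] = np.real(t[i, j]) / (2.0 * delta * gaps[i, j])
    return out, flagged


def matrix_derivative(m_plus, m_minus, s_plus, s_minus, delta: float, scheme: str):
    """Central difference of a state-pair property matrix (SOC, dipole).

    ``scheme='adiabatic'`` differences the matrices directly; ``'diabatic'``
    transforms each displaced matrix into the reference basis first.
    """
    if scheme == "adiabatic":
        return (np.asarray(m_plus) - np.asarray(m_minus)) / (2.0 * delta)
    if scheme == "diabatic":
        # S M S^H expresses the displaced property matrix in the basis of the
        # reference adiabatic states (S rows index the reference states), so
        # the difference isolates the diabatic variation of the property.
        sp, sm = np.asarray(s_plus), np.asarray(s_minus)
        return (
            sp @ np.asarray(m_plus) @ sp.conj().T
            - sm @ np.asarray(m_minus) @ sm.conj().T
        ) / (2.0 * delta)
    raise ValueError(f"unknown scheme {scheme!r}")


def fix_overlap_phases(s):
    """Sign-fix overlap columns so every diagonal element is non-negative.

    Returns ``(s_fixed, flips, warnings)``: the per-column sign record and a
    list of state-tracking warnings for columns whose diagonal magnitude is
    below 0.5 (the displaced state no longer resembles the reference one).
    """
    s = np.array(s)
    n = s.shape[0]
    flips = np.ones(n)
    warnings = []
    for j in range(n):
        if np.real(s[j, j]) < 0:
            flips[j] = -1.0
            s[:, j] = -s[:, j]
        if abs(s[j, j]) < 0.5:
            warnings.append(
                f"state {j + 1}: |S_jj| = {abs(s[j, j]):.3f} < 0.5, "
                "state tracking unreliable"
            )
    return s, flips, warnings


# ---------------------------------------------------------------------------
# The hybrid interface
# ---------------------------------------------------------------------------

@register_interface
class NumDiffInterface(HybridInterface):
    """Numerical-differentiation parent over one electronic-structure child.

    Template keys: ``child <interface_id> <template>``, ``delta <float>``,
    ``scheme adiabatic|diabatic``, ``properties grad nacdr socdr dmdr``,
    ``phase_fix on|off``.  Programmatically, add the reference child under
    the name ``"ref"`` before ``finalize``; one displaced child per
    Cartesian coordinate is cloned from it (each reused for the + and -
    displacements, so the child-call count per step is 1 + 6*n_atoms).

    Feature negotiation: the child must provide ``h``; ``nacdr`` and the
    diabatic scheme additionally require ``overlap``.  The parent then
    advertises the derivative capabilities on top of the child's own set.
    """

    interface_id = "numdiff"

    def __init__(self, name=None):
        super().__init__(name)
        self.config = NumDiffConfig()
        self._warnings: list[str] = []

    # -- setup -----------------------------------------------------------
    def _build_children(self) -> None:
        tpl = self.qmin.template
        if "ref" not in self.children:
            spec = tpl.get("child")
            if spec is None:
                raise NegotiationError(f"{self.name}: no child configured")
            child_id, child_tpl = (spec if isinstance(spec, (list, tuple)) else (spec, None))
            self._make_child(child_id, child_tpl, "ref")
        self.config = NumDiffConfig(
            delta=float(tpl.get("delta", 0.01)),
            scheme=str(tpl.get("scheme", "adiabatic")),
            properties=tuple(
                tpl["properties"].split()
                if isinstance(tpl.get("properties"), str)
                else tpl.get("properties", ("grad", "nacdr"))
            ),
            phase_fix=tpl.get("phase_fix", True) not in (False, "off", 0),
        )
        ref = self.children["ref"]
        ref_template = ref.qmin.template or getattr(ref, "_pending_template", None)
        # one displaced child per coordinate, cloned from the reference child
        for a in range(self.qmin.molecule.n_atoms):
            for d in _DIRS:
                name = f"disp(a={a},d={d})"
                clone = type(ref)(name=name)
                clone._pending_template = ref_template
                self.add_child(name, clone)

    def _child_features(self) -> FeatureSet:
        child = self.children.get("ref")
        if child is None:
            return FeatureSet()
        return child.get_features()

    def _features(self) -> FeatureSet:
        feats = set(self._child_features())
        if "h" in feats:
            feats |= {"grad", "socdr"}
            if "overlap" in feats:
                feats.add("nacdr")
        if "dm" in feats:
            feats.add("dmdr")
        return FeatureSet(feats)

    def _finalize(self) -> None:
        child_feats = self._child_features()
        needed = {"h"}
        if self.config.scheme == "diabatic" or "nacdr" in self.config.properties:
            needed.add("overlap")
        child_feats.require(needed, who=f"{self.name} child")

    # -- execution -------------------------------------------------------
    def _execute(self) -> QMout:
        cfg = self.config
        req = self.qmin.requests
        mol = self.qmin.molecule
        step = req.step
        R = self.qmin.coords.positions
        pc = (
            self.qmin.coords.point_charge_positions,
            self.qmin.coords.point_charge_values,
        )

        want = set(req.tokens())
        deriv = {t for t in ("grad", "nacdr", "socdr", "dmdr") if t in want}
        need_overlap = cfg.scheme == "diabatic" or "nacdr" in deriv
        need_dm = "dmdr" in deriv or "dm" in want

        # reference run: energies (and dipoles) at R, wave function saved
        ref_req = RequestSet(hamiltonian=True, dipoles=need_dm, step=step)
        ref = self.children["ref"]
        try:
            ref_out = ref.single_point(self._coords(R, pc), ref_req).copy()
        except Exception as exc:
            raise ChildError.wrap(self.name, "ref", exc) from exc

        energies = ref_out.energies
        gaps = energies[:, None] - energies[None, :]
        n = mol.n_total
        nat = mol.n_atoms
        delta = cfg.delta

        disp_req = RequestSet(
            hamiltonian=True, overlaps=need_overlap, dipoles=need_dm, step=step
        )

        grad = np.zeros((n, nat, 3))
        nacdr = np.zeros((n, n, nat, 3))
        socdr = np.zeros((n, n, nat, 3), complex)
        dmdr = np.zeros((3, n, n, nat, 3))
        flagged_pairs: set = set()

        disps = make_displacements(R, delta)
        per_coord: dict[tuple, dict] = {}
        for (a, d, sign), geom in disps:
            child = self.children[f"disp(a={a},d={d})"]
            if need_overlap:
                # anchor all overlaps at the reference wave function
                try:
                    anchor = ref.save.get(step, "wavefunction")
                except Exception as exc:  # backend without a saved wf
                    raise ChildError.wrap(self.name, "ref", exc) from exc
                child.save.put(step, "ref_wavefunction", anchor)
                child.qmin.control["overlap_anchor_step"] = step
                child.qmin.control["overlap_anchor_label"] = "ref_wavefunction"
            try:
                out = child.single_point(self._coords(geom, pc), disp_req).copy()
            except Exception as exc:
                raise ChildError.wrap(
                    self.name, f"disp(a={a},d={d},{sign})", exc
                ) from exc
            per_coord.setdefault((a, d), {})[sign] = out

        for (a, d), pair in per_coord.items():
            di = _DIRS.index(d)
            hp, hm = pair["+"].h, pair["-"].h
            sp = sm = None
            if need_overlap:
                sp, sm = pair["+"].s, pair["-"].s
                if cfg.phase_fix:
                    sp, _, warn_p = fix_overlap_phases(sp)
                    sm, _, warn_m = fix_overlap_phases(sm)
                    for w in warn_p + warn_m:
                        self.qmout_warn(f"disp(a={a},d={d}): {w}")

            if "grad" in deriv:
                if cfg.scheme == "adiabatic":
                    grad[:, a, di] = grad_adiabatic(hp, hm, delta)
                else:
                    grad[:, a, di] = grad_diabatic(sp, hp, sm, hm, delta)
            if "nacdr" in deriv:
                if cfg.scheme == "adiabatic":
                    nacdr[:, :, a, di] = nac_adiabatic(sp, sm, delta)
                else:
                    val, flagged = nac_diabatic(sp, hp, sm, hm, delta, gaps)
                    nacdr[:, :, a, di] = val
                    flagged_pairs.update(flagged)
            if "socdr" in deriv:
                soc = matrix_derivative(hp, hm, sp, sm, delta, cfg.scheme)
                np.fill_diagonal(soc, 0.0)  # diagonal belongs to gradients
                socdr[:, :, a, di] = soc
            if "dmdr" in deriv:
                for p in range(3):
                    dmdr[p, :, :, a, di] = np.real(
                        matrix_derivative(
                            pair["+"].dm[p], pair["-"].dm[p], sp, sm, delta, cfg.scheme
                        )
                    )

        q = allocate_qmout(mol, req)
        if req.hamiltonian:
            q.h[:] = ref_out.h
        if req.dipoles:
            q.dm[:] = ref_out.dm
        if "grad" in deriv:
            q.grad[:] = grad
        if "nacdr" in deriv:
            q.nacdr[:] = nacdr
            if flagged_pairs:
                q.metadata["nacdr_flagged"] = sorted(flagged_pairs)
        if "socdr" in deriv:
            q.socdr[:] = socdr
        if "dmdr" in deriv:
            q.dmdr[:] = dmdr
        if self._warnings:
            q.metadata["warnings"] = list(self._warnings)
            self._warnings.clear()
        return q

    def qmout_warn(self, msg: str) -> None:
        self._warnings.append(msg)
        self.log.warning(msg)

    @staticmethod
    def _coords(R, pc) -> Coordinates:
        return Coordinates(np.asarray(R, float), pc[0], pc[1])
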