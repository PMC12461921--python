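"""Subtractive QM/MM with electrostatic embedding as a hybrid interface.

The ONIOM-like subtractive scheme runs three children:

* ``MML`` -- the MM child on the entire ("large") system,
* ``MMS`` -- the MM child restricted to the QM ("small") region, run
  charge-free,
* ``QM``  -- the electronic child on the QM region, polarized by the MM
  atoms' partial charges as external point charges (the charges come from
  the MML child's charge list restricted to the MM atoms).

Energies combine as  H_total = H_QM + (E_MML - E_MMS) * I  over all
sublevels (the MM contribution is state-independent), and gradients as

    QM-atom rows:  g_QM + g_MML[qm] - g_MMS
    MM-atom rows:  g_MML[mm] + dE_QM/d(point-charge positions)

so the assembled gradient is the exact derivative of the assembled energy
whenever the children's gradients are exact.  Nonadiabatic couplings pass
through from the QM child on QM atoms and are zero on MM atoms.  The QM
region must be a set of complete molecules: bonds crossing the boundary
are rejected (no link atoms in this version).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import HybridInterface, register_interface
from .containers import (
    Coordinates,
    FeatureSet,
    MoleculeSpec,
    QMout,
    RequestSet,
    allocate_qmout,
)
from .errors import MappingError, NegotiationError
from .models import MMInterface, load_mm_model

__all__ = [
    "RegionMap",
    "split_geometry",
    "combine_energies",
    "combine_gradients",
    "QMMMInterface",
]


@dataclass
class RegionMap:
    """Partition of the full atom list into a QM region and its MM complement."""

    qm_atoms: list[int]
    n_atoms: int

    def __post_init__(self):
        self.qm_atoms = [int(a) for a in self.qm_atoms]
        if not self.qm_atoms:
            raise MappingError("QM region must contain at least one atom")
        if len(set(self.qm_atoms)) != len(self.qm_atoms):
            raise MappingError("QM region indices overlap (duplicates)")
        bad = [a for a in self.qm_atoms if not 0 <= a < self.n_atoms]
        if bad:
            raise MappingError(f"QM region indices out of range: {bad}")

    @property
    def mm_atoms(self) -> list[int]:
        inside = set(self.qm_atoms)
        return [a for a in range(self.n_atoms) if a not in inside]


def split_geometry(full_coords: np.ndarray, region: RegionMap, mm_charges: np.ndarray):
    """QM-region coordinates plus the MM atoms as external point charges.

    ``mm_charges`` is the full-system charge list (the MML child's); only
    the MM-atom entries are used as embedding charges.
    """
    full = np.asarray(full_coords, float).reshape(region.n_atoms, 3)
    qm = full[region.qm_atoms]
    mm = region.mm_atoms
    pc_pos = full[mm]
    pc_val = np.asarray(mm_charges, float)[mm]
    return qm, pc_pos, pc_val


def combine_energies(e_mml: float, e_mms: float, h_qm: np.ndarray) -> np.ndarray:
    """Subtractive total Hamiltonian: H_QM + (E_MML - E_MMS) * I."""
    h = np.array(h_qm, complex)
    h[np.diag_indices(h.shape[0])] += e_mml - e_mms
    return h


def combine_gradients(
    g_mml: np.ndarray,
    g_mms: np.ndarray,
    g_qm: np.ndarray,
    g_qm_on_pc: np.ndarray | None,
    region: RegionMap,
) -> np.ndarray:
    """Back-map per-state child gradients onto the full system.

    Shapes: g_mml (n_atoms, 3); g_mms, g_qm (n_states, n_qm, 3);
    g_qm_on_pc (n_states, n_mm, 3) or None when the QM child was run
    without embedding charges.
    """
    g_qm = np.asarray(g_qm, float)
    n_states = g_qm.shape[0]
    out = np.tile(np.asarray(g_mml, float)[None, :, :], (n_states, 1, 1))
    out[:, region.qm_atoms, :] += g_qm - np.asarray(g_mms, float)
    if g_qm_on_pc is not None and region.mm_atoms:
        out[:, region.mm_atoms, :] += np.asarray(g_qm_on_pc, float)
    return out


@register_interface
class QMMMInterface(HybridInterface):
    """Subtractive QM/MM parent (children ``QM``, ``MML``, ``MMS``).

    Template keys: ``qm_child <id> <template>``, ``mm_child <id> <template>``,
    ``qm_atoms <0-based indices>``, optional ``embedding on|off``.  The MMS
    model is derived automatically by restricting the MM child's model to
    the QM region (with charges switched off).
    """

    interface_id = "qmmm"

    def __init__(self, name=None):
        super().__init__(name)
        self.region: RegionMap | None = None
        self.embedding = True

    # -- setup -----------------------------------------------------------
    def _build_children(self) -> None:
        tpl = self.qmin.template
        mol = self.qmin.molecule
        qm_atoms = tpl.get("qm_atoms")
        if qm_atoms is None:
            raise MappingError(f"{self.name}: template lacks 'qm_atoms'")
        if isinstance(qm_atoms, (int, np.integer)):
            qm_atoms = [qm_atoms]
        self.region = RegionMap(list(qm_atoms), mol.n_atoms)
        self.embedding = tpl.get("embedding", True) not in (False, "off", 0)

        mm_spec = tpl.get("mm_child")
        qm_spec = tpl.get("qm_child")
        if mm_spec is None or qm_spec is None:
            raise NegotiationError(f"{self.name}: template needs qm_child and mm_child")
        mm_id, mm_tpl = mm_spec if isinstance(mm_spec, (list, tuple)) else (mm_spec, None)
        qm_id, qm_tpl = qm_spec if isinstance(qm_spec, (list, tuple)) else (qm_spec, None)

        mml = self._make_child(mm_id, mm_tpl, "MML")
        if not isinstance(mml, MMInterface):
            raise NegotiationError(
                f"{self.name}: mm_child must be an MM interface, got {mm_id!r}"
            )
        mms_model = mml.model.restrict(self.region.qm_atoms)
        if self.embedding and self.region.mm_atoms:
            # MMS runs charge-free: QM-region electrostatics live in the QM child
            mms_model.charges = np.zeros_like(mms_model.charges)
        self._make_child("mm_model", {"model_object": mms_model}, "MMS")
        self._make_child(qm_id, qm_tpl, "QM")

        if self.embedding and self.region.mm_atoms:
            if "returns_point_charges" not in self.children["MML"].get_features():
                raise NegotiationError(
                    f"{self.name}: MM child must return partial charges "
                    "(returns_point_charges) for embedding"
                )
            if "accepts_point_charges" not in self.children["QM"].get_features():
                raise NegotiationError(
                    f"{self.name}: QM child cannot accept point charges; "
                    "set 'embedding off' for mechanical embedding"
                )

    def _child_molecule(self, child) -> MoleculeSpec:
        mol = self.qmin.molecule
        if child.name == "MML":
            return MoleculeSpec(mol.elements, [1])
        if child.name == "MMS":
            return MoleculeSpec([mol.elements[a] for a in self.region.qm_atoms], [1])
        n_pc = len(self.region.mm_atoms) if self.embedding else 0
        return MoleculeSpec(
            [mol.elements[a] for a in self.region.qm_atoms],
            mol.states_per_mult,
            mol.charge_per_mult,
            n_point_charges=n_pc,
        )

    def _features(self) -> FeatureSet:
        qm = self.children.get("QM")
        if qm is None:
            return FeatureSet()
        feats = set(qm.get_features()) - {"accepts_point_charges"}
        if self.region and self.region.mm_atoms and self.embedding:
            qm_feats = qm.get_features()
            if "grad_pc" not in qm_feats and "grad" in feats:
                # cannot assemble full-system gradients without point-charge forces
                feats.discard("grad")
        return FeatureSet(feats)

    # -- execution -------------------------------------------------------
    def _execute(self) -> QMout:
        mol = self.qmin.molecule
        req = self.qmin.requests
        region = self.region
        step = req.step
        full = self.qmin.coords.positions

        mm_req = RequestSet(hamiltonian=True, gradients="all", step=step)
        mml_out = self.run_children({"MML": (Coordinates(full), mm_req)})["MML"]
        mm_charges = mml_out.atom_charges
        qm_pos, pc_pos, pc_val = split_geometry(full, region, mm_charges)
        mms_out = self.run_children({"MMS": (Coordinates(qm_pos), mm_req.copy())})["MMS"]

        qm_req = req.copy()
        want_grad = bool(req.gradients)
        if want_grad:
            qm_req.gradients = "all"
        qm_req.hamiltonian = True
        if self.embedding and region.mm_atoms:
            qm_req.point_charge_derivatives = want_grad
            qm_coords = Coordinates(qm_pos, pc_pos, pc_val)
        else:
            qm_coords = Coordinates(qm_pos)
        qm_out = self.run_children({"QM": (qm_coords, qm_req)})["QM"]

        e_mml = float(np.real(mml_out.h[0, 0]))
        e_mms = float(np.real(mms_out.h[0, 0]))

        q = allocate_qmout(mol, req)
        if req.hamiltonian:
            q.h[:] = combine_energies(e_mml, e_mms, qm_out.h)
        if want_grad:
            g_pc = qm_out.grad_pc if (self.embedding and region.mm_atoms) else None
            q.grad[:] = combine_gradients(
                mml_out.grad[0], mms_out.grad[0], qm_out.grad, g_pc, region
            )
        if req.nac_vectors:
            q.nacdr[:, :, region.qm_atoms, :] = qm_out.nacdr
        if req.dipoles:
            q.dm[:] = qm_out.dm
        if req.overlaps:
            q.s[:] = qm_out.s
        q.prop0d.append(("E_MM_large", e_mml))
        q.prop0d.append(("E_MM_small", e_mms))
        q.prop0d.append(("E_MM", e_mml - e_mms))
        self.save.put(step, "mm_energies", (e_mml, e_mms))
        self.save.garbage_collect(step)
        return q
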