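"""Standardized input (QMin) and output (QMout) data containers.

``QMin`` collects everything an interface needs to run: the molecule
definition, current coordinates, the request list, save/step bookkeeping
and the interface-private template/resources maps.  ``QMout`` carries the
results: Hamiltonian, overlaps, dipoles, gradient/coupling tensors and
free-form properties, all indexed by the canonical sublevel ordering of
:mod:`esi.states` and stored in Hartree atomic units.

Only requested tensors are allocated, so memory use follows the request
list, and the presence of an attribute doubles as the "was this computed"
flag.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields

import numpy as np

from .errors import AllocationError, InvalidMoleculeError, NegotiationError
from .states import build_state_map, count_total_states

__all__ = [
    "MoleculeSpec",
    "Coordinates",
    "RequestSet",
    "FeatureSet",
    "QMin",
    "QMout",
    "allocate_qmout",
    "REQUEST_TOKENS",
    "MODE_TOKENS",
    "CAPABILITY_VOCABULARY",
]

#: Capability tokens an interface can be asked for (request vocabulary).
REQUEST_TOKENS = frozenset(
    {
        "h",
        "grad",
        "overlap",
        "nacdr",
        "dm",
        "socdr",
        "dmdr",
        "grad_pc",
        "nacdr_pc",
        "socdr_pc",
        "dmdr_pc",
        "density",
        "property",
    }
)

#: Mode tokens describing how an interface can be embedded in a call tree.
MODE_TOKENS = frozenset(
    {"accepts_point_charges", "returns_point_charges", "returns_densities"}
)

CAPABILITY_VOCABULARY = REQUEST_TOKENS | MODE_TOKENS


@dataclass
class MoleculeSpec:
    """Static definition of the system: atoms, state space, charges."""

    elements: list[str]
    states_per_mult: list[int]
    charge_per_mult: list[int] | None = None
    n_point_charges: int = 0

    def __post_init__(self):
        self.elements = list(self.elements)
        self.states_per_mult = [int(n) for n in self.states_per_mult]
        if self.charge_per_mult is None:
            self.charge_per_mult = [0] * len(self.states_per_mult)
        if len(self.charge_per_mult) != len(self.states_per_mult):
            raise InvalidMoleculeError(
                "charge_per_mult and states_per_mult must have equal length"
            )
        # validates non-negativity / not-all-zero
        count_total_states(self.states_per_mult)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_total(self) -> int:
        """Total number of sublevels across all multiplets."""
        return count_total_states(self.states_per_mult)

    @property
    def state_map(self):
        return build_state_map(self.states_per_mult)


@dataclass
class Coordinates:
    """Geometries in Bohr: molecular positions plus optional point charges."""

    positions: np.ndarray
    point_charge_positions: np.ndarray | None = None
    point_charge_values: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.point_charge_positions is not None:
            self.point_charge_positions = np.asarray(
                self.point_charge_positions, dtype=float
            ).reshape(-1, 3)
            self.point_charge_values = np.asarray(
                self.point_charge_values, dtype=float
            ).ravel()
            if len(self.point_charge_values) != len(self.point_charge_positions):
                raise InvalidMoleculeError(
                    "point charge values and positions differ in length"
                )

    @property
    def n_point_charges(self) -> int:
        if self.point_charge_positions is None:
            return 0
        return len(self.point_charge_positions)

    def validate(self, molecule: MoleculeSpec) -> None:
        if len(self.positions) != molecule.n_atoms:
            raise InvalidMoleculeError(
                f"{len(self.positions)} coordinates for {molecule.n_atoms} atoms"
            )
        if self.n_point_charges != molecule.n_point_charges:
            raise InvalidMoleculeError(
                f"{self.n_point_charges} point charges, molecule declares "
                f"{molecule.n_point_charges}"
            )


@dataclass
class RequestSet:
    """Which electronic quantities the caller needs at the current step.

    ``gradients`` is either ``None`` (not requested), the string ``"all"``,
    or a list of 1-based sublevel indices.
    """

    hamiltonian: bool = False
    gradients: str | list[int] | None = None
    overlaps: bool = False
    nac_vectors: bool = False
    dipoles: bool = False
    soc_derivatives: bool = False
    dipole_derivatives: bool = False
    point_charge_derivatives: bool = False
    densities: bool = False
    properties: bool = False
    step: int = 0
    is_restart: bool = False

    _TOKEN_FIELDS = {
        "hamiltonian": "h",
        "gradients": "grad",
        "overlaps": "overlap",
        "nac_vectors": "nacdr",
        "dipoles": "dm",
        "soc_derivatives": "socdr",
        "dipole_derivatives": "dmdr",
        "point_charge_derivatives": "grad_pc",
        "densities": "density",
        "properties": "property",
    }

    def tokens(self) -> frozenset[str]:
        """Capability tokens implied by the active requests."""
        out = set()
        for attr, token in self._TOKEN_FIELDS.items():
            if getattr(self, attr):
                out.add(token)
        return frozenset(out)

    def gradient_states(self, n_total: int) -> list[int]:
        """Resolve the gradient request to explicit 1-based sublevel indices."""
        if not self.gradients:
            return []
        if self.gradients == "all":
            return list(range(1, n_total + 1))
        idx = [int(i) for i in self.gradients]
        bad = [i for i in idx if not 1 <= i <= n_total]
        if bad:
            raise AllocationError(f"gradient state indices out of range: {bad}")
        return idx

    def copy(self) -> "RequestSet":
        return copy.deepcopy(self)


class FeatureSet(frozenset):
    """Declared capabilities of an interface (request + mode tokens).

    Used for negotiation: a caller checks its request tokens against the
    feature set before running, and hybrid parents derive their own feature
    set from their children's.
    """

    def __new__(cls, tokens=()):
        tokens = frozenset(tokens)
        unknown = tokens - CAPABILITY_VOCABULARY
        if unknown:
            raise ValueError(f"unknown capability tokens: {sorted(unknown)}")
        return super().__new__(cls, tokens)

    def missing(self, needed) -> frozenset[str]:
        return frozenset(needed) - self

    def require(self, needed, who: str = "interface") -> None:
        missing = self.missing(needed)
        if missing:
            raise NegotiationError(
                f"{who} cannot satisfy request(s): {sorted(missing)}", missing
            )


@dataclass
class QMin:
    """Hierarchical input container handed to an interface.

    ``molecule``, ``coords``, ``requests`` and ``save`` are caller-provided;
    ``template`` and ``resources`` are interface-private configuration;
    ``maps``/``scheduling``/``control`` are optional driver hints.
    """

    molecule: MoleculeSpec
    coords: Coordinates | None = None
    requests: RequestSet = field(default_factory=RequestSet)
    save: dict = field(default_factory=dict)
    template: dict = field(default_factory=dict)
    resources: dict = field(default_factory=dict)
    maps: dict = field(default_factory=dict)
    scheduling: dict = field(default_factory=dict)
    control: dict = field(default_factory=dict)


# QMout tensor catalogue: attribute -> (request token, shape builder, dtype)
def _qmout_shapes(n: int, na: int, npc: int):
    return {
        "h": ("h", (n, n), complex),
        "s": ("overlap", (n, n), complex),
        "dm": ("dm", (3, n, n), float),
        "grad": ("grad", (n, na, 3), float),
        "nacdr": ("nacdr", (n, n, na, 3), float),
        "socdr": ("socdr", (n, n, na, 3), complex),
        "dmdr": ("dmdr", (3, n, n, na, 3), float),
        "grad_pc": ("grad_pc", (n, npc, 3), float),
        "nacdr_pc": ("nacdr_pc", (n, n, npc, 3), float),
        "socdr_pc": ("socdr_pc", (n, n, npc, 3), complex),
        "dmdr_pc": ("dmdr_pc", (3, n, n, npc, 3), float),
    }


class QMout:
    """Result container; only requested tensors exist as attributes.

    Dimension metadata (``n_total``, ``n_atoms``, ``n_point_charges``,
    ``states_per_mult``, ``charge_per_mult``) is always present.  Property
    channels ``prop0d``/``prop1d``/``prop2d`` hold labeled scalars,
    per-state vectors and per-state-pair matrices.  ``metadata`` is a free
    map for timings, convergence notes and state-tracking warnings.
    """

    TENSOR_NAMES = tuple(_qmout_shapes(1, 1, 1))

    def __init__(
        self,
        n_total: int,
        n_atoms: int,
        n_point_charges: int = 0,
        states_per_mult=None,
        charge_per_mult=None,
    ):
        self.n_total = int(n_total)
        self.n_atoms = int(n_atoms)
        self.n_point_charges = int(n_point_charges)
        self.states_per_mult = list(states_per_mult) if states_per_mult else None
        self.charge_per_mult = list(charge_per_mult) if charge_per_mult else None
        self.prop0d: list[tuple[str, float]] = []
        self.prop1d: list[tuple[str, np.ndarray]] = []
        self.prop2d: list[tuple[str, np.ndarray]] = []
        self.atom_charges: np.ndarray | None = None  # returns_point_charges mode
        self.basis_info: dict | None = None
        self.densities: dict | None = None
        self.metadata: dict = {}

    # -- allocation ------------------------------------------------------
    def allocate(self, names) -> "QMout":
        """Zero-allocate the named tensors with shape checks."""
        catalogue = _qmout_shapes(self.n_total, self.n_atoms, self.n_point_charges)
        for name in names:
            if name not in catalogue:
                raise AllocationError(f"unknown QMout tensor {name!r}")
            _, shape, dtype = catalogue[name]
            if any(s < 0 for s in shape):
                raise AllocationError(f"negative dimension for {name}: {shape}")
            setattr(self, name, np.zeros(shape, dtype=dtype))
        return self

    def has(self, name: str) -> bool:
        return hasattr(self, name)

    def allocated(self) -> list[str]:
        return [t for t in self.TENSOR_NAMES if self.has(t)]

    # -- convenience -----------------------------------------------------
    @property
    def energies(self) -> np.ndarray:
        """Real diagonal of the Hamiltonian (adiabatic energies, Hartree)."""
        return np.real(np.diag(self.h))

    def check_shapes(self) -> None:
        catalogue = _qmout_shapes(self.n_total, self.n_atoms, self.n_point_charges)
        for name, (_, shape, _) in catalogue.items():
            if self.has(name) and getattr(self, name).shape != shape:
                raise AllocationError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )

    def check_hermitian(self, tol: float = 1e-10) -> float:
        """Max |H - H^dagger|; raises if above tol."""
        dev = float(np.max(np.abs(self.h - self.h.conj().T))) if self.n_total else 0.0
        if dev > tol:
            raise AllocationError(f"Hamiltonian not Hermitian: max deviation {dev:.3e}")
        return dev

    def copy(self) -> "QMout":
        return copy.deepcopy(self)

    def __repr__(self):
        return (
            f"QMout(n_total={self.n_total}, n_atoms={self.n_atoms}, "
            f"tensors={self.allocated()})"
        )


def allocate_qmout(molecule: MoleculeSpec, requests: RequestSet) -> QMout:
    """Build a QMout holding exactly the tensors the request set implies."""
    q = QMout(
        molecule.n_total,
        molecule.n_atoms,
        molecule.n_point_charges,
        molecule.states_per_mult,
        molecule.charge_per_mult,
    )
    names = []
    if requests.hamiltonian:
        names.append("h")
    if requests.gradients:
        requests.gradient_states(molecule.n_total)  # validates indices
        names.append("grad")
    if requests.overlaps:
        names.append("s")
    if requests.nac_vectors:
        names.append("nacdr")
    if requests.dipoles:
        names.append("dm")
    if requests.soc_derivatives:
        names.append("socdr")
    if requests.dipole_derivatives:
        names.append("dmdr")
    if requests.point_charge_derivatives:
        names.extend(["grad_pc", "nacdr_pc"])
    return q.allocate(names)
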