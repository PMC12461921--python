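"""Text dialects: QM.in-style input, QM.out-style output, xyz and configs.

The QM.in/QM.out dialect is self-consistent within this package (it is not
byte-compatible with any external program's save format):

* QM.in: an xyz block (count, comment, ``element x y z`` lines, Angstrom by
  default), followed by keyword lines (``states``, ``charge``, ``unit``,
  request keywords ``h``/``grad``/``overlap``/``nacdr``/``dm``, ``step N``,
  ``point_charges <file>``).
* QM.out: keyword blocks ``! <id> <name> <dim1> <dim2> ... [complex]``
  followed by whitespace-separated numbers (15 significant digits; complex
  entries as paired re/im columns).  The header block retains the states
  per multiplicity, charge per multiplicity and atom counts, so a file is
  self-descriptive.
* Flat key/value config files with ``#`` comments for templates/resources.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .constants import ANGSTROM_TO_BOHR
from .containers import MoleculeSpec, Coordinates, RequestSet, QMout
from .errors import ParseError

__all__ = [
    "read_qmin_file",
    "write_qmout",
    "read_qmout",
    "read_xyz_frames",
    "read_keyvalue_config",
]

_FMT = "%.15e"

_BLOCK_IDS = {
    "h": 1,
    "dm": 2,
    "grad": 3,
    "s": 5,
    "nacdr": 6,
    "socdr": 7,
    "dmdr": 8,
    "grad_pc": 9,
    "nacdr_pc": 10,
    "socdr_pc": 11,
    "dmdr_pc": 12,
}


# ---------------------------------------------------------------------------
# QM.out
# ---------------------------------------------------------------------------

def _write_array(fh, arr: np.ndarray) -> None:
    is_complex = np.iscomplexobj(arr)
    flat = arr.reshape(-1, arr.shape[-1]) if arr.ndim > 1 else arr.reshape(1, -1)
    for row in flat:
        if is_complex:
            fh.write(
                " ".join(f"{_FMT % v.real} {_FMT % v.imag}" for v in row) + "\n"
            )
        else:
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def write_qmout(q: QMout, destination) -> None:
    """Write a QMout to ``destination`` (path or open text handle)."""
    if hasattr(destination, "write"):
        _write_qmout_fh(q, destination)
    else:
        with open(destination, "w") as fh:
            _write_qmout_fh(q, fh)


def _write_qmout_fh(q: QMout, fh) -> None:
    fh.write("! 0 header\n")
    if q.states_per_mult is not None:
        fh.write("states " + " ".join(str(n) for n in q.states_per_mult) + "\n")
    if q.charge_per_mult is not None:
        fh.write("charge " + " ".join(str(c) for c in q.charge_per_mult) + "\n")
    fh.write(f"ntotal {q.n_total}\n")
    fh.write(f"natom {q.n_atoms}\n")
    fh.write(f"npc {q.n_point_charges}\n")
    for name, block_id in _BLOCK_IDS.items():
        if not q.has(name):
            continue
        arr = getattr(q, name)
        dims = " ".join(str(d) for d in arr.shape)
        tag = " complex" if np.iscomplexobj(arr) else ""
        fh.write(f"! {block_id} {name} {dims}{tag}\n")
        _write_array(fh, arr)
    if q.atom_charges is not None:
        fh.write(f"! 13 atom_charges {len(q.atom_charges)}\n")
        _write_array(fh, np.asarray(q.atom_charges, float))
    for block_id, cname in ((20, "prop0d"), (21, "prop1d"), (22, "prop2d")):
        entries = getattr(q, cname)
        if not entries:
            continue
        fh.write(f"! {block_id} {cname} {len(entries)}\n")
        for label, value in entries:
            arr = np.atleast_1d(np.asarray(value, float))
            dims = " ".join(str(d) for d in arr.shape)
            fh.write(f'label "{label}" {dims}\n')
            _write_array(fh, arr)
    if q.metadata:
        fh.write("! 30 metadata\n")
        fh.write(json.dumps(q.metadata, default=str) + "\n")


class _Lines:
    """Line cursor that remembers position for parse errors."""

    def __init__(self, text: str, source: str | None):
        self.lines = text.splitlines()
        self.pos = 0
        self.source = source

    def peek(self):
        return self.lines[self.pos] if self.pos < len(self.lines) else None

    def next(self):
        line = self.peek()
        if line is None:
            raise ParseError("unexpected end of file", self.pos, self.source)
        self.pos += 1
        return line

    def error(self, msg):
        raise ParseError(msg, self.pos, self.source)


def _read_numbers(cur: _Lines, count: int, block: str) -> np.ndarray:
    vals: list[float] = []
    while len(vals) < count:
        line = cur.peek()
        if line is None or line.startswith("!"):
            cur.error(
                f"truncated block '{block}': expected {count} numbers, got {len(vals)}"
            )
        cur.next()
        try:
            vals.extend(float(tok) for tok in line.split())
        except ValueError:
            cur.error(f"non-numeric data in block '{block}'")
    if len(vals) != count:
        cur.error(f"block '{block}' has {len(vals)} numbers, expected {count}")
    return np.array(vals)


def read_qmout(source) -> QMout:
    """Read a QM.out dialect file back into a QMout."""
    if hasattr(source, "read"):
        text, name = source.read(), getattr(source, "name", None)
    else:
        with open(source) as fh:
            text = fh.read()
        name = str(source)
    cur = _Lines(text, name)
    header = cur.peek()
    if header is None or not header.startswith("! 0 header"):
        cur.error("missing '! 0 header' block")
    cur.next()
    meta: dict[str, list[int]] = {}
    while (line := cur.peek()) is not None and not line.startswith("!"):
        cur.next()
        toks = line.split()
        if not toks:
            continue
        try:
            meta[toks[0]] = [int(t) for t in toks[1:]]
        except ValueError:
            cur.error(f"malformed header line {line!r}")
    for key in ("ntotal", "natom", "npc"):
        if key not in meta:
            cur.error(f"header lacks '{key}'")
    q = QMout(
        meta["ntotal"][0],
        meta["natom"][0],
        meta["npc"][0],
        meta.get("states"),
        meta.get("charge"),
    )
    while (line := cur.peek()) is not None:
        if not line.strip():
            cur.next()
            continue
        if not line.startswith("!"):
            cur.error(f"expected block header, got {line!r}")
        toks = line.split()
        if len(toks) < 3:
            cur.error(f"malformed block header {line!r}")
        cur.next()
        name_tok = toks[2]
        if name_tok in _BLOCK_IDS:
            is_complex = toks[-1] == "complex"
            dims = tuple(int(t) for t in (toks[3:-1] if is_complex else toks[3:]))
            count = int(np.prod(dims)) * (2 if is_complex else 1)
            raw = _read_numbers(cur, count, name_tok)
            if is_complex:
                raw = raw[0::2] + 1j * raw[1::2]
            setattr(q, name_tok, raw.reshape(dims))
        elif name_tok == "atom_charges":
            q.atom_charges = _read_numbers(cur, int(toks[3]), name_tok)
        elif name_tok in ("prop0d", "prop1d", "prop2d"):
            n_entries = int(toks[3])
            out = getattr(q, name_tok)
            for _ in range(n_entries):
                lab_line = cur.next()
                if not lab_line.startswith("label"):
                    cur.error(f"expected property label line in {name_tok}")
                label = lab_line.split('"')[1]
                dims = tuple(int(t) for t in lab_line.split('"')[2].split())
                arr = _read_numbers(cur, int(np.prod(dims)), name_tok).reshape(dims)
                if name_tok == "prop0d":
                    out.append((label, float(arr.ravel()[0])))
                else:
                    out.append((label, arr))
        elif name_tok == "metadata":
            q.metadata = json.loads(cur.next())
        else:
            cur.error(f"unknown block '{name_tok}'")
    q.check_shapes()
    return q


# ---------------------------------------------------------------------------
# QM.in and xyz
# ---------------------------------------------------------------------------

_REQUEST_KEYWORDS = {"h", "overlap", "nacdr", "dm", "socdr", "dmdr", "density", "property"}


def read_qmin_file(path) -> tuple[MoleculeSpec, Coordinates, RequestSet]:
    """Parse a QM.in dialect file (geometry + keywords)."""
    with open(path) as fh:
        text = fh.read()
    cur = _Lines(text, str(path))
    try:
        n_atoms = int(cur.next().split()[0])
    except (ValueError, IndexError):
        cur.error("first line must be the atom count")
    cur.next()  # comment
    elements, pos = [], []
    for _ in range(n_atoms):
        toks = cur.next().split()
        if len(toks) < 4:
            cur.error("atom line needs 'element x y z'")
        elements.append(toks[0])
        try:
            pos.append([float(t) for t in toks[1:4]])
        except ValueError:
            cur.error("non-numeric coordinate")
    unit = "angstrom"
    states = None
    charge = None
    req = RequestSet()
    pc_file = None
    while (line := cur.peek()) is not None:
        cur.next()
        line = line.split("#")[0].strip()
        if not line:
            continue
        toks = line.split()
        key = toks[0].lower()
        if key == "unit":
            unit = toks[1].lower()
            if unit not in ("angstrom", "bohr"):
                cur.error(f"unknown unit {unit!r}")
        elif key == "states":
            states = [int(t) for t in toks[1:]]
        elif key == "charge":
            charge = [int(t) for t in toks[1:]]
        elif key == "grad":
            if len(toks) == 1 or toks[1].lower() == "all":
                req.gradients = "all"
            else:
                req.gradients = [int(t) for t in toks[1:]]
        elif key == "step":
            req.step = int(toks[1])
        elif key == "restart":
            req.is_restart = True
        elif key == "point_charges":
            pc_file = toks[1]
        elif key in _REQUEST_KEYWORDS:
            attr = {
                "h": "hamiltonian",
                "overlap": "overlaps",
                "nacdr": "nac_vectors",
                "dm": "dipoles",
                "socdr": "soc_derivatives",
                "dmdr": "dipole_derivatives",
                "density": "densities",
                "property": "properties",
            }[key]
            setattr(req, attr, True)
        else:
            cur.error(f"unknown keyword {key!r}")
    if states is None:
        cur.error("missing 'states' keyword")
    scale = ANGSTROM_TO_BOHR if unit == "angstrom" else 1.0
    positions = np.array(pos) * scale
    pc_pos = pc_val = None
    if pc_file is not None:
        pc_path = os.path.join(os.path.dirname(os.path.abspath(path)), pc_file)
        raw = np.loadtxt(pc_path, ndmin=2)
        pc_pos, pc_val = raw[:, :3] * scale, raw[:, 3]
    mol = MoleculeSpec(
        elements,
        states,
        charge,
        n_point_charges=0 if pc_pos is None else len(pc_pos),
    )
    coords = Coordinates(positions, pc_pos, pc_val)
    coords.validate(mol)
    return mol, coords, req


def read_xyz_frames(path, unit: str = "angstrom"):
    """Read a (multi-frame) xyz file -> (elements, list of Bohr coordinate arrays)."""
    scale = ANGSTROM_TO_BOHR if unit == "angstrom" else 1.0
    with open(path) as fh:
        text = fh.read()
    cur = _Lines(text, str(path))
    elements = None
    frames = []
    while cur.peek() is not None:
        if not cur.peek().strip():
            cur.next()
            continue
        try:
            n = int(cur.next().split()[0])
        except (ValueError, IndexError):
            cur.error("expected atom count at frame start")
        cur.next()
        elems, pos = [], []
        for _ in range(n):
            toks = cur.next().split()
            elems.append(toks[0])
            pos.append([float(t) for t in toks[1:4]])
        if elements is None:
            elements = elems
        elif elems != elements:
            cur.error("frames have inconsistent elements")
        frames.append(np.array(pos) * scale)
    if elements is None:
        raise ParseError("empty xyz file", source=str(path))
    return elements, frames


def read_keyvalue_config(path) -> list[tuple[str, list[str]]]:
    """Read a flat key/value config file; '#' starts a comment.

    Returns ordered (key, tokens) pairs; keys may repeat (e.g. several
    ``advisor`` lines in a committee template).
    """
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            toks = line.split()
            out.append((toks[0].lower(), toks[1:]))
    return out
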