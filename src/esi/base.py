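"""Interface base classes: lifecycle, save/step management, child trees.

Every electronic-structure interface follows one strict lifecycle so that
expensive initialization happens once, not at every time step::

    setup_molecule -> read_template -> read_resources -> finalize
    then per step: set_coords, set_requests, run, get_qmout

Hybrid interfaces own named child interfaces and lead them recursively
through the same lifecycle; child failures propagate as :class:`ChildError`
carrying the name path through the tree (``parent/child/grandchild``).

"Fast" interfaces keep their save data in memory and only flush to disk on
demand, which removes filesystem overhead for analytic/ML backends that are
called thousands of times per trajectory.
"""

from __future__ import annotations

import enum
import io
import logging
import os
import pickle
import sys
from abc import ABC, abstractmethod

import numpy as np

from .containers import (
    Coordinates,
    FeatureSet,
    MoleculeSpec,
    QMin,
    QMout,
    RequestSet,
)
from .errors import ChildError, LifecycleError, NegotiationError, SaveLookupError
from .fileio import read_keyvalue_config

__all__ = [
    "Phase",
    "StepKind",
    "SaveRegistry",
    "detect_step_kind",
    "negotiate_features",
    "Interface",
    "FastInterface",
    "HybridInterface",
    "AbInitioInterface",
    "attach_logger",
    "register_interface",
    "get_interface_class",
    "available_interfaces",
]


class Phase(enum.IntEnum):
    CREATED = 0
    MOLECULE_SET = 1
    TEMPLATE_READ = 2
    RESOURCES_READ = 3
    READY = 4
    RAN = 5


class StepKind(enum.Enum):
    NEW_STEP = "new_step"
    REPEAT_STEP = "repeat_step"
    RESTART = "restart"
    INCONSISTENT = "inconsistent"


# ---------------------------------------------------------------------------
# Save registry
# ---------------------------------------------------------------------------

class SaveRegistry:
    """Step-resolved persistence store.

    Every payload is assigned to exactly one (step, label) slot.  The most
    recent successfully completed step is tracked separately so a caller can
    classify an incoming step request (new / repeated / restart).  Old
    entries are garbage-collected by a retention window unless flagged
    persistent.  The in-memory mode is used by fast interfaces and flushed
    to ``SAVE/<step>/<label>`` files (plus a ``SAVE/STEP`` file holding the
    last successful step) only on demand.
    """

    STEP_FILE = "STEP"

    def __init__(self):
        self.entries: dict[tuple[int, str], object] = {}
        self.persistent: set[tuple[int, str]] = set()
        self.collected: set[tuple[int, str]] = set()
        self.last_successful_step: int | None = None
        self.freshly_loaded = False

    def put(self, step: int, label: str, payload, persistent: bool = False) -> None:
        if step < 0:
            raise ValueError("step must be non-negative")
        key = (int(step), str(label))
        self.entries[key] = payload
        self.collected.discard(key)
        if persistent:
            self.persistent.add(key)

    def get(self, step: int, label: str):
        key = (int(step), str(label))
        if key in self.entries:
            return self.entries[key]
        if key in self.collected:
            raise SaveLookupError(
                f"save entry {key} was garbage-collected", collected=True
            )
        raise SaveLookupError(f"save entry {key} was never stored", collected=False)

    def garbage_collect(self, current_step: int, retain_window: int = 2) -> list:
        """Drop entries older than ``current_step - retain_window + 1``.

        The default window keeps the current and previous step.  Persistent
        entries are never collected.  Returns the removed keys.
        """
        cutoff = current_step - retain_window + 1
        removed = [
            key
            for key in self.entries
            if key[0] < cutoff and key not in self.persistent
        ]
        for key in removed:
            del self.entries[key]
            self.collected.add(key)
        return removed

    # -- disk persistence ------------------------------------------------
    def flush(self, savedir: str) -> None:
        os.makedirs(savedir, exist_ok=True)
        for (step, label), payload in self.entries.items():
            stepdir = os.path.join(savedir, str(step))
            os.makedirs(stepdir, exist_ok=True)
            with open(os.path.join(stepdir, label), "wb") as fh:
                pickle.dump(
                    {"payload": payload, "persistent": (step, label) in self.persistent},
                    fh,
                )
        if self.last_successful_step is not None:
            with open(os.path.join(savedir, self.STEP_FILE), "w") as fh:
                fh.write(f"{self.last_successful_step}\n")

    @classmethod
    def load(cls, savedir: str) -> "SaveRegistry":
        reg = cls()
        step_file = os.path.join(savedir, cls.STEP_FILE)
        if os.path.exists(step_file):
            with open(step_file) as fh:
                reg.last_successful_step = int(fh.read().split()[0])
        for entry in sorted(os.listdir(savedir)):
            stepdir = os.path.join(savedir, entry)
            if not (entry.isdigit() and os.path.isdir(stepdir)):
                continue
            for label in sorted(os.listdir(stepdir)):
                with open(os.path.join(stepdir, label), "rb") as fh:
                    rec = pickle.load(fh)
                reg.put(int(entry), label, rec["payload"], rec["persistent"])
        reg.freshly_loaded = True
        return reg


def detect_step_kind(requested_step: int, registry: SaveRegistry) -> StepKind:
    """Classify an incoming step request against the save registry."""
    last = registry.last_successful_step
    if registry.freshly_loaded:
        return StepKind.RESTART
    if last is None:
        return StepKind.NEW_STEP if requested_step == 0 else StepKind.INCONSISTENT
    if requested_step == last + 1:
        return StepKind.NEW_STEP
    if requested_step == last:
        return StepKind.REPEAT_STEP
    return StepKind.INCONSISTENT


def negotiate_features(needed, child_features: FeatureSet, who: str = "child") -> FeatureSet:
    """Check required capability tokens against a feature set.

    Raises :class:`NegotiationError` naming the missing capabilities;
    returns the feature set unchanged on success so hybrid parents can
    chain derivations.
    """
    child_features.require(needed, who)
    return child_features


# ---------------------------------------------------------------------------
# Logging redirection
# ---------------------------------------------------------------------------

_VERBOSITY = {"quiet": logging.ERROR, "normal": logging.INFO, "debug": logging.DEBUG}


def attach_logger(interface: "Interface", sink=None, verbosity: str = "normal") -> None:
    """Redirect one interface's log output to its own sink.

    ``sink`` may be a path, an open stream, or None for standard output.
    Each interface owns a non-propagating logger, so messages from one
    interface never interleave into another interface's sink.
    """
    log = interface.log
    for handler in list(log.handlers):
        log.removeHandler(handler)
        handler.close()
    if sink is None:
        handler = logging.StreamHandler(sys.stdout)
    elif isinstance(sink, (str, os.PathLike)):
        handler = logging.FileHandler(sink)
    else:
        handler = logging.StreamHandler(sink)
    handler.setFormatter(logging.Formatter(f"[{interface.name}] %(message)s"))
    log.addHandler(handler)
    log.setLevel(_VERBOSITY.get(verbosity, logging.INFO))


# ---------------------------------------------------------------------------
# Interface registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, type] = {}


def register_interface(cls):
    """Class decorator registering an interface under its ``interface_id``."""
    _REGISTRY[cls.interface_id] = cls
    return cls


def get_interface_class(interface_id: str) -> type:
    try:
        return _REGISTRY[interface_id]
    except KeyError:
        raise KeyError(
            f"unknown interface id {interface_id!r}; known: {sorted(_REGISTRY)}"
        ) from None


def available_interfaces() -> list[str]:
    return sorted(_REGISTRY)


# ---------------------------------------------------------------------------
# Interface base class
# ---------------------------------------------------------------------------

class Interface(ABC):
    """Abstract electronic-structure interface.

    Subclasses implement ``_features`` (declared capabilities), ``_finalize``
    (one-time setup) and ``_execute`` (fill a QMout for the current QMin).
    The base class enforces lifecycle order, validates requests against the
    feature set, manages step bookkeeping and exposes the three overridable
    setup hooks (``get_features``, ``setup_dialog``, ``prepare_folder``).
    """

    interface_id = "abstract"

    def __init__(self, name: str | None = None):
        self.name = name or self.interface_id
        self.phase = Phase.CREATED
        self.qmin = QMin(molecule=None)  # type: ignore[arg-type]
        self.qmout: QMout | None = None
        self.save = SaveRegistry()
        self.log = logging.getLogger(f"esi.{self.name}.{id(self):x}")
        self.log.propagate = False
        if not self.log.handlers:
            self.log.addHandler(logging.NullHandler())
        self._run_count = 0

    # -- lifecycle guards ------------------------------------------------
    def _advance(self, expected: Phase, new: Phase, what: str) -> None:
        if self.phase != expected:
            raise LifecycleError(
                f"{self.name}: {what} called in phase {self.phase.name}, "
                f"expected {expected.name}"
            )
        self.phase = new

    # -- setup hooks (overridable) --------------------------------------
    def get_features(self) -> FeatureSet:
        """Declared capabilities; callable at any lifecycle phase."""
        return self._features()

    def setup_dialog(self) -> dict:
        """Hook for interactive setup tools; returns suggested template keys."""
        return {}

    def prepare_folder(self, path: str) -> None:
        """Hook for setup tools preparing a run folder."""
        os.makedirs(path, exist_ok=True)

    # -- initialization (once) ------------------------------------------
    def setup_molecule(self, molecule: MoleculeSpec) -> "Interface":
        self._advance(Phase.CREATED, Phase.MOLECULE_SET, "setup_molecule")
        self.qmin.molecule = molecule
        return self

    def read_template(self, source=None) -> "Interface":
        """Accepts a dict, a path to a flat key/value file, or None."""
        self._advance(Phase.MOLECULE_SET, Phase.TEMPLATE_READ, "read_template")
        self.qmin.template = self._load_config(source)
        return self

    def read_resources(self, source=None) -> "Interface":
        self._advance(Phase.TEMPLATE_READ, Phase.RESOURCES_READ, "read_resources")
        self.qmin.resources = self._load_config(source)
        savedir = self.qmin.resources.get("savedir")
        if savedir and os.path.exists(os.path.join(savedir, SaveRegistry.STEP_FILE)):
            self.save = SaveRegistry.load(savedir)
            self.log.info(
                "reloaded save data, last successful step %s",
                self.save.last_successful_step,
            )
        return self

    @staticmethod
    def _load_config(source) -> dict:
        if source is None:
            return {}
        if isinstance(source, dict):
            return dict(source)
        cfg: dict = {}
        for key, toks in read_keyvalue_config(source):
            parsed: object
            vals = []
            for t in toks:
                try:
                    vals.append(int(t))
                except ValueError:
                    try:
                        vals.append(float(t))
                    except ValueError:
                        vals.append(t)
            parsed = vals[0] if len(vals) == 1 else vals
            if not vals:
                parsed = True
            if key in cfg:  # repeatable keys accumulate
                prev = cfg[key]
                cfg[key] = (prev if isinstance(prev, list) and key in _REPEATABLE else [prev]) + [parsed]
            else:
                cfg[key] = [parsed] if key in _REPEATABLE else parsed
        return cfg

    def finalize(self) -> "Interface":
        self._advance(Phase.RESOURCES_READ, Phase.READY, "finalize")
        self._finalize()
        return self

    # -- per-step --------------------------------------------------------
    def set_coords(self, coords) -> "Interface":
        if self.phase < Phase.READY:
            raise LifecycleError(f"{self.name}: set_coords before finalize")
        if not isinstance(coords, Coordinates):
            coords = Coordinates(np.asarray(coords, float))
        coords.validate(self.qmin.molecule)
        self.qmin.coords = coords
        return self

    def set_requests(self, requests: RequestSet) -> "Interface":
        if self.phase < Phase.READY:
            raise LifecycleError(f"{self.name}: set_requests before finalize")
        self.get_features().require(requests.tokens(), who=self.name)
        self.qmin.requests = requests
        return self

    def run(self) -> "Interface":
        if self.phase < Phase.READY:
            raise LifecycleError(f"{self.name}: run before finalize")
        if self.qmin.coords is None:
            raise LifecycleError(f"{self.name}: run before set_coords")
        requests = self.qmin.requests
        self.get_features().require(requests.tokens(), who=self.name)
        kind = detect_step_kind(requests.step, self.save)
        self.qmin.control["step_kind"] = kind
        self.save.freshly_loaded = False
        self.log.info("run step %d (%s)", requests.step, kind.value)
        self.qmout = self._execute()
        self.qmout.metadata.setdefault("interface", self.name)
        self.qmout.metadata.setdefault("step", requests.step)
        self.save.last_successful_step = requests.step
        self._run_count += 1
        self.phase = Phase.RAN
        return self

    def get_qmout(self) -> QMout:
        if self.qmout is None:
            raise LifecycleError(f"{self.name}: get_qmout before run")
        return self.qmout

    # -- single-point convenience ---------------------------------------
    def single_point(self, coords, requests: RequestSet) -> QMout:
        self.set_coords(coords)
        self.set_requests(requests)
        self.run()
        return self.get_qmout()

    # -- to be implemented ----------------------------------------------
    @abstractmethod
    def _features(self) -> FeatureSet: ...

    def _finalize(self) -> None:  # pragma: no cover - default no-op
        pass

    @abstractmethod
    def _execute(self) -> QMout: ...


_REPEATABLE = {"advisor"}


class FastInterface(Interface):
    """Base for cheap backends (analytic models, ML surrogates).

    Save data lives in memory; ``flush_save``/``read_resources`` provide the
    end-of-run flush and restart reload.  Fast interfaces are scheduled on
    the minimal-overhead (serial, in-process) queue by hybrid parents.
    """

    fast = True

    def flush_save(self, savedir: str | None = None) -> None:
        savedir = savedir or self.qmin.resources.get("savedir")
        if not savedir:
            raise LifecycleError(f"{self.name}: no savedir configured for flush")
        self.save.flush(savedir)


class HybridInterface(Interface):
    """Base for interfaces that orchestrate child interfaces.

    Children are registered by role name before ``finalize`` (or built from
    the template by ``_build_children``); ``finalize`` recursively leads
    every child through its own initialization.  ``run_children`` executes
    a set of per-child requests and wraps any child exception with the
    child's name path.
    """

    fast = False

    def __init__(self, name: str | None = None):
        super().__init__(name)
        self.children: dict[str, Interface] = {}

    def add_child(self, name: str, child: Interface) -> Interface:
        if name in self.children:
            raise ValueError(f"duplicate child name {name!r} under {self.name}")
        self.children[name] = child
        child.name = f"{name}"
        return child

    def finalize(self) -> "HybridInterface":
        self._advance(Phase.RESOURCES_READ, Phase.READY, "finalize")
        self._build_children()
        for child in self.children.values():
            if child.phase == Phase.CREATED:
                child.setup_molecule(self._child_molecule(child))
            if child.phase == Phase.MOLECULE_SET:
                child.read_template(getattr(child, "_pending_template", None))
            if child.phase == Phase.TEMPLATE_READ:
                child.read_resources(None)
            if child.phase == Phase.RESOURCES_READ:
                child.finalize()
        self._finalize()
        return self

    def _build_children(self) -> None:
        """Hook: construct children from template keys if none were added."""

    def _child_molecule(self, child: Interface) -> MoleculeSpec:
        """Molecule spec handed to auto-initialized children (default: own)."""
        return self.qmin.molecule

    def run_children(self, jobs: dict[str, tuple]) -> dict[str, QMout]:
        """Run ``{name: (coords, requests)}`` on the named children.

        Results are keyed by child name and independent of execution order.
        Child exceptions are re-raised as :class:`ChildError` with the full
        name path.  Fast children go through the serial in-process queue;
        heavier children would go through a parallelizable queue — the
        scheduling is hidden behind this call and results are order-free.
        """
        results: dict[str, QMout] = {}
        for cname, (coords, requests) in jobs.items():
            child = self.children[cname]
            try:
                results[cname] = child.single_point(coords, requests).copy()
            except Exception as exc:
                raise ChildError.wrap(self.name, cname, exc) from exc
        return results

    def _make_child(self, interface_id: str, template, name: str) -> Interface:
        child = get_interface_class(interface_id)(name=name)
        self.add_child(name, child)
        child.setup_molecule(self._child_molecule(child))
        child.read_template(template)
        child.read_resources(None)
        child.finalize()
        return child


class AbInitioInterface(Interface):
    """Stub base for interfaces that launch external quantum-chemistry codes.

    Real subclasses would prepare input files, schedule subprocess jobs on a
    parallel queue honoring core/memory resources, and parse program output;
    none of that machinery ships here.  The class exists to anchor the
    inheritance layout (fast vs ab initio vs hybrid) and the scheduling-queue
    contract: jobs submitted via ``schedule_jobs`` may complete in any order
    and results are returned keyed by job id.
    """

    fast = False

    def schedule_jobs(self, jobs: dict[str, callable]) -> dict[str, object]:
        return {job_id: fn() for job_id, fn in jobs.items()}

    def _features(self) -> FeatureSet:  # pragma: no cover - stub
        return FeatureSet()

    def _execute(self) -> QMout:  # pragma: no cover - stub
        raise NotImplementedError(
            "ab initio interfaces require an external program wrapper"
        )
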