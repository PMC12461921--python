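"""Workflow hybrids: fallback, adaptive-sampling committee, database recorder.

These interfaces add control flow, not electronic structure:

* **Adaptive sampling** runs one "leader" child and one or more "advisor"
  children on the same geometry and compares configured result attributes
  (by default the adiabatic energies, mean-absolute-error metric).  If no
  advisor deviates beyond threshold, the leader's results are passed on
  unchanged, ensuring consistent potential-energy surfaces along a
  trajectory; otherwise a :class:`DeviationError` is raised — intentional
  control flow for the caller (typically a fallback parent).

* **Fallback** first calls a "trial" child and passes its results through
  on success; on failure (crash or committee deviation) it calls a
  "backup" child instead and counts consecutive trial failures.  Reaching
  the configured count raises :class:`TrajectoryTermination`, the signal a
  dynamics driver uses to abort the trajectory.

* **Database** transparently records every geometry and result received
  from its child to an append-only store before passing it on — placed
  under the backup path of a fallback tree, it collects exactly the
  reference calculations an active-learning loop wants as new training
  points.
"""

from __future__ import annotations

import importlib.util
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np

from .base import HybridInterface, register_interface
from .containers import FeatureSet, QMout
from .errors import (
    ChildError,
    ComparisonError,
    DeviationError,
    NegotiationError,
    StorageError,
    TrajectoryTermination,
)

__all__ = [
    "DeviationPolicy",
    "FallbackPolicy",
    "deviation",
    "RecordStore",
    "db_append",
    "db_read",
    "AdaptiveSamplingInterface",
    "FallbackInterface",
    "DatabaseInterface",
]


# ---------------------------------------------------------------------------
# Deviation metrics
# ---------------------------------------------------------------------------

def _mae(a, b):
    return float(np.mean(np.abs(a - b)))


def _rmsd(a, b):
    return float(np.sqrt(np.mean(np.abs(a - b) ** 2)))


def _max(a, b):
    return float(np.max(np.abs(a - b)))


_METRICS = {"mae": _mae, "rmsd": _rmsd, "max": _max}

# QMout attribute extractors available for comparison
_EXTRACTORS = {
    "energies": lambda q: q.energies,
    "hamiltonian": lambda q: q.energies,  # alias: diagonal of H
    "h_full": lambda q: np.asarray(q.h),
    "grad": lambda q: np.asarray(q.grad),
    "dm": lambda q: np.asarray(q.dm),
    "nacdr": lambda q: np.asarray(q.nacdr),
}


def _load_custom_metric(path: str):
    """Load ``metric(a, b) -> float`` from a Python source file."""
    spec = importlib.util.spec_from_file_location("esi_custom_metric", path)
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod.metric


@dataclass
class DeviationPolicy:
    """Per-attribute thresholds and error metrics for committee comparison.

    ``thresholds`` maps attribute name -> positive threshold (units of the
    attribute, e.g. Hartree for energies); ``metrics`` maps attribute ->
    'mae' | 'rmsd' | 'max' | callable | 'custom:<path>'.  The default policy
    compares the Hamiltonian diagonal (adiabatic energies) with an MAE
    threshold of 0.8 mHartree (22 meV).
    """

    thresholds: dict = field(default_factory=lambda: {"energies": 0.0008})
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        for attr, thr in self.thresholds.items():
            if attr not in _EXTRACTORS:
                raise ComparisonError(f"unknown comparison attribute {attr!r}")
            if not thr > 0:
                raise ComparisonError(f"threshold for {attr!r} must be positive")

    def metric_for(self, attr: str):
        m = self.metrics.get(attr, "mae")
        if callable(m):
            return m
        if isinstance(m, str) and m.startswith("custom:"):
            return _load_custom_metric(m.split(":", 1)[1])
        try:
            return _METRICS[m]
        except KeyError:
            raise ComparisonError(f"unknown metric {m!r} for {attr!r}") from None


@dataclass
class FallbackPolicy:
    """Abort after this many consecutive trial failures."""

    max_consecutive_failures: int = 2

    def __post_init__(self):
        if self.max_consecutive_failures < 1:
            raise ValueError("max_consecutive_failures must be positive")


def deviation(leader: QMout, advisor: QMout, policy: DeviationPolicy) -> dict:
    """Per-attribute deviation of an advisor from the leader.

    Returns ``{attribute: (value, exceeded)}``; raises ComparisonError on
    shape mismatch.  Only configured attributes are compared — never an
    implicit full-object diff.
    """
    out = {}
    for attr, thr in policy.thresholds.items():
        a = _EXTRACTORS[attr](leader)
        b = _EXTRACTORS[attr](advisor)
        if np.shape(a) != np.shape(b):
            raise ComparisonError(
                f"attribute {attr!r}: leader shape {np.shape(a)} != advisor "
                f"shape {np.shape(b)}"
            )
        value = policy.metric_for(attr)(np.asarray(a), np.asarray(b))
        if value < 0:
            raise ComparisonError(f"metric for {attr!r} returned negative value")
        out[attr] = (value, value > thr)
    return out


# ---------------------------------------------------------------------------
# Record store
# ---------------------------------------------------------------------------

class RecordStore:
    """Append-only store of (geometry, results) records.

    Records are JSON objects (one per line when backed by a file) with the
    schema: ``step``, ``timestamp``, ``geometry`` (n_atoms x 3, Bohr),
    ``tensors`` (every populated QMout tensor, complex ones as re/im pairs),
    ``props`` (labeled scalars) — the same fields an atomic-simulation
    database row would carry, so exporting is a mapping, not a dependency.
    In-memory when no path is given.
    """

    def __init__(self, path: str | None = None):
        self.path = path
        self.records: list[dict] = []
        if path and os.path.exists(path):
            self.records = self._read_file(path)

    @staticmethod
    def _read_file(path) -> list[dict]:
        try:
            with open(path) as fh:
                return [json.loads(line) for line in fh if line.strip()]
        except (OSError, json.JSONDecodeError) as exc:
            raise StorageError(f"cannot read record store {path}: {exc}") from exc

    @staticmethod
    def _encode(arr: np.ndarray):
        arr = np.asarray(arr)
        if np.iscomplexobj(arr):
            return {"re": arr.real.tolist(), "im": arr.imag.tolist()}
        return arr.tolist()

    @staticmethod
    def _decode(obj):
        if isinstance(obj, dict):
            return np.asarray(obj["re"]) + 1j * np.asarray(obj["im"])
        return np.asarray(obj, float)

    def append(self, geometry: np.ndarray, qmout: QMout, step: int) -> dict:
        record = {
            "step": int(step),
            "timestamp": time.time(),
            "geometry": np.asarray(geometry, float).reshape(-1, 3).tolist(),
            "tensors": {
                name: self._encode(getattr(qmout, name))
                for name in qmout.allocated()
            },
            "props": [[label, float(v)] for label, v in qmout.prop0d],
        }
        if self.path:
            try:
                with open(self.path, "a") as fh:
                    fh.write(json.dumps(record) + "\n")
            except OSError as exc:
                raise StorageError(
                    f"record store {self.path} unwritable: {exc}"
                ) from exc
        self.records.append(record)
        return record

    def read(self) -> list[dict]:
        if self.path:
            return self._read_file(self.path)
        return list(self.records)

    def __len__(self):
        return len(self.records)


def db_append(store: RecordStore, geometry, qmout: QMout, step: int = 0) -> dict:
    return store.append(geometry, qmout, step)


def db_read(store: RecordStore) -> list[dict]:
    return store.read()


# ---------------------------------------------------------------------------
# Interfaces
# ---------------------------------------------------------------------------

@register_interface
class AdaptiveSamplingInterface(HybridInterface):
    """Leader/advisor committee with per-attribute deviation thresholds.

    Template keys: ``leader <id> <template>``, ``advisor <id> <template>``
    (repeatable), ``threshold <attribute> <value>``, ``metric <attribute>
    mae|rmsd|max|custom:<path>``.  Any advisor exceeding any configured
    threshold raises :class:`DeviationError` carrying the offending
    attributes and measured values; otherwise the leader's QMout is
    returned unchanged.
    """

    interface_id = "adaptive"

    def __init__(self, name=None):
        super().__init__(name)
        self.policy = DeviationPolicy()

    def _advisor_names(self):
        return sorted(n for n in self.children if n.startswith("advisor"))

    def _build_children(self) -> None:
        tpl = self.qmin.template
        if "leader" not in self.children:
            lid, ltpl = tpl["leader"]
            self._make_child(lid, ltpl, "leader")
            advisors = tpl.get("advisor", [])
            if advisors and not isinstance(advisors[0], (list, tuple)):
                advisors = [advisors]
            for k, (aid, atpl) in enumerate(advisors):
                self._make_child(aid, atpl, "advisor" if k == 0 else f"advisor{k + 1}")
        if not self._advisor_names():
            raise NegotiationError(f"{self.name}: at least one advisor required")
        thresholds, metrics = {}, {}
        thr = tpl.get("threshold")
        if thr:
            pairs = thr if isinstance(thr[0], (list, tuple)) else [thr]
            for attr, value in pairs:
                thresholds[attr] = float(value)
        met = tpl.get("metric")
        if met:
            pairs = met if isinstance(met[0], (list, tuple)) else [met]
            for attr, mname in pairs:
                metrics[attr] = mname
        if thresholds:
            self.policy = DeviationPolicy(thresholds, metrics)

    def _features(self) -> FeatureSet:
        leader = self.children.get("leader")
        if leader is None:
            return FeatureSet()
        feats = set(leader.get_features())
        for aname in self._advisor_names():
            feats &= set(self.children[aname].get_features())
        return FeatureSet(feats)

    def _execute(self) -> QMout:
        coords = self.qmin.coords
        req = self.qmin.requests
        names = ["leader"] + self._advisor_names()
        results = self.run_children({n: (coords, req.copy()) for n in names})
        leader_out = results["leader"]
        offending: dict[str, float] = {}
        for aname in self._advisor_names():
            for attr, (value, exceeded) in deviation(
                leader_out, results[aname], self.policy
            ).items():
                if exceeded:
                    offending[f"{aname}:{attr}"] = max(
                        value, offending.get(f"{aname}:{attr}", 0.0)
                    )
        if offending:
            raise DeviationError(offending)
        return leader_out


@register_interface
class FallbackInterface(HybridInterface):
    """Trial/backup pair with consecutive-failure counting.

    Template keys: ``trial <id> <template>``, ``backup <id> <template>``,
    ``max_consecutive_failures <int>``.  A trial success passes its results
    through and resets the counter; a trial failure increments it and falls
    back to the backup child (whose result is trusted unconditionally).
    When the counter reaches the maximum, :class:`TrajectoryTermination` is
    raised instead — a signal, distinct from an error.
    """

    interface_id = "fallback"

    def __init__(self, name=None):
        super().__init__(name)
        self.policy = FallbackPolicy()
        self.consecutive_failures = 0
        self.events: list[tuple[int, str]] = []  # (step, 'trial'|'backup')

    def _build_children(self) -> None:
        tpl = self.qmin.template
        if "trial" not in self.children:
            tid, ttpl = tpl["trial"]
            bid, btpl = tpl["backup"]
            self._make_child(tid, ttpl, "trial")
            self._make_child(bid, btpl, "backup")
        if "max_consecutive_failures" in tpl:
            self.policy = FallbackPolicy(int(tpl["max_consecutive_failures"]))

    def _features(self) -> FeatureSet:
        trial = self.children.get("trial")
        backup = self.children.get("backup")
        if trial is None or backup is None:
            return FeatureSet()
        return FeatureSet(set(trial.get_features()) & set(backup.get_features()))

    def _execute(self) -> QMout:
        coords = self.qmin.coords
        req = self.qmin.requests
        step = req.step
        try:
            out = self.run_children({"trial": (coords, req.copy())})["trial"]
        except ChildError as exc:
            self.consecutive_failures += 1
            if isinstance(exc.original, DeviationError):
                self.log.info(
                    "step %d: committee deviation (%s), falling back", step, exc.original
                )
            else:
                self.log.warning("step %d: trial child crashed (%s)", step, exc)
            if self.consecutive_failures >= self.policy.max_consecutive_failures:
                raise TrajectoryTermination(
                    f"trial failed in {self.consecutive_failures} consecutive "
                    f"steps (limit {self.policy.max_consecutive_failures})",
                    step=step,
                ) from exc
            out = self.run_children({"backup": (coords, req.copy())})["backup"]
            self.events.append((step, "backup"))
            return out
        self.consecutive_failures = 0
        self.events.append((step, "trial"))
        return out


@register_interface
class DatabaseInterface(HybridInterface):
    """Transparent recorder: child results are stored, then passed on.

    Template keys: ``child <id> <template>``, ``db_path <file>`` (JSON-lines
    store; in-memory when omitted).  The returned QMout is numerically
    identical to the child's; a storage failure raises before pass-through
    so training data is never lost silently.
    """

    interface_id = "database"

    def __init__(self, name=None):
        super().__init__(name)
        self.store = RecordStore()

    def _build_children(self) -> None:
        tpl = self.qmin.template
        if "child" not in self.children:
            cid, ctpl = tpl["child"]
            self._make_child(cid, ctpl, "child")
        if tpl.get("db_path"):
            self.store = RecordStore(tpl["db_path"])

    def _features(self) -> FeatureSet:
        child = self.children.get("child")
        return FeatureSet() if child is None else child.get_features()

    def _execute(self) -> QMout:
        coords = self.qmin.coords
        req = self.qmin.requests
        out = self.run_children({"child": (coords, req.copy())})["child"]
        self.store.append(coords.positions, out, req.step)
        return out
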