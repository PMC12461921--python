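"""Call-tree construction and driver harnesses.

A tree config describes a (possibly nested) interface tree as structured
text (YAML) mapping directly onto the registry::

    interface: fallback
    template: {max_consecutive_failures: 2}
    children:
      trial:
        interface: adaptive
        children:
          leader:  {interface: lvc_model, template: {paramfile: model.yaml}}
          advisor: {interface: lvc_model, template: {paramfile: model2.yaml}}
      backup:
        interface: database
        template: {db_path: records.jsonl}
        children:
          child: {interface: lvc_model, template: {paramfile: model.yaml}}

``build_tree`` instantiates and initializes the whole tree;
``run_single_point`` executes one QM.in -> QM.out cycle, and
``run_sequence`` feeds a geometry series through the tree with proper
step/save bookkeeping (this is a caller harness, not a propagator:
geometries are inputs, never integrated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .base import HybridInterface, Interface, get_interface_class
from .containers import Coordinates, MoleculeSpec, QMout, RequestSet
from .errors import EsiError, TrajectoryTermination
from .fileio import read_qmin_file, write_qmout

__all__ = ["TreeConfig", "build_tree", "run_single_point", "run_sequence"]


@dataclass
class TreeConfig:
    """Nested interface-tree description (root id, template, named children)."""

    interface: str
    template: dict | str | None = None
    children: dict = field(default_factory=dict)

    @classmethod
    def from_any(cls, source) -> "TreeConfig":
        """Accepts a TreeConfig, a mapping, or a YAML file path."""
        if isinstance(source, TreeConfig):
            return source
        if not isinstance(source, dict):
            with open(source) as fh:
                source = yaml.safe_load(fh)
        return cls._from_dict(source, seen=())

    @classmethod
    def _from_dict(cls, d: dict, seen: tuple) -> "TreeConfig":
        if "interface" not in d:
            raise EsiError("tree config node lacks 'interface'")
        get_interface_class(d["interface"])  # must be registered
        if len(seen) > 32:
            raise EsiError("tree config nesting too deep (cycle?)")
        children = {
            name: cls._from_dict(sub, seen + (d["interface"],))
            for name, sub in (d.get("children") or {}).items()
        }
        return cls(d["interface"], d.get("template"), children)


def build_tree(
    config, molecule: MoleculeSpec, resources: dict | None = None
) -> Interface:
    """Instantiate and fully initialize an interface tree.

    The root is led through the complete lifecycle (molecule, template,
    resources, finalize); children declared in the config are attached
    before finalization so the root initializes them recursively.
    """
    cfg = TreeConfig.from_any(config)
    root = get_interface_class(cfg.interface)(name=cfg.interface)
    _attach_children(root, cfg)
    root.setup_molecule(molecule)
    root.read_template(cfg.template)
    root.read_resources(resources)
    root.finalize()
    return root


def _attach_children(node: Interface, cfg: TreeConfig) -> None:
    if not cfg.children:
        return
    if not isinstance(node, HybridInterface):
        raise EsiError(f"interface {cfg.interface!r} cannot hold children")
    for name, sub in cfg.children.items():
        child = get_interface_class(sub.interface)(name=name)
        child._pending_template = sub.template
        _attach_children(child, sub)
        node.add_child(name, child)


def run_single_point(tree_config, qmin_file, qmout_file) -> QMout:
    """Standalone execution: read QM.in dialect, run the tree, write QM.out."""
    molecule, coords, requests = read_qmin_file(qmin_file)
    root = build_tree(tree_config, molecule)
    out = root.single_point(coords, requests)
    write_qmout(out, qmout_file)
    return out


def run_sequence(
    root, geometry_series, requests: RequestSet, molecule: MoleculeSpec | None = None
):
    """Feed a geometry series through a call tree, one time step per frame.

    ``root`` is a finalized interface (or a tree config, in which case
    ``molecule`` must be given).  Steps are numbered 0..n-1 and the tree's
    save/step bookkeeping advances accordingly, so overlap-consuming
    interfaces see consecutive-step wave-function data.  A
    :class:`TrajectoryTermination` signal from the tree stops the sequence;
    the partial results are returned together with the stop reason.

    Returns ``(list of QMout, stop_reason or None)``.
    """
    if not isinstance(root, Interface):
        if molecule is None:
            raise EsiError("run_sequence needs a MoleculeSpec when given a config")
        root = build_tree(root, molecule)
    results: list[QMout] = []
    stop_reason = None
    for step, geom in enumerate(geometry_series):
        req = requests.copy()
        req.step = step
        if step > 0:
            req.overlaps = requests.overlaps  # consecutive-step overlaps only
        elif requests.overlaps:
            req.overlaps = False  # no previous wave function at step 0
        try:
            results.append(root.single_point(np.asarray(geom, float), req))
        except TrajectoryTermination as sig:
            stop_reason = str(sig)
            break
    return results, stop_reason
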