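"""Exception hierarchy.

Interfaces signal failure by raising; hybrid parents wrap child exceptions
with the child's name path so errors can be traced through nested call
trees (e.g. ``QMMM/QM/LVC``).  Two exception types are intentional control
flow rather than failures: :class:`DeviationError` (committee disagreement)
and :class:`TrajectoryTermination` (abort signal after repeated failures).
"""

from __future__ import annotations


class EsiError(Exception):
    """Base class for all package errors."""


class InvalidMoleculeError(EsiError):
    """Inconsistent molecule specification (states, elements, shapes)."""


class AllocationError(EsiError):
    """A requested result tensor is not representable for the dimensions."""


class ParseError(EsiError):
    """Malformed dialect/config file; carries file context and line number."""

    def __init__(self, message: str, line: int | None = None, source: str | None = None):
        loc = ""
        if source is not None:
            loc += f" in {source}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)
        self.line = line
        self.source = source


class LifecycleError(EsiError):
    """Interface lifecycle routine called out of order."""


class NegotiationError(EsiError):
    """Requested capability missing from an interface's feature set."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = frozenset(missing)


class SaveLookupError(EsiError, KeyError):
    """Missing save entry; distinguishes never-stored from garbage-collected."""

    def __init__(self, message: str, collected: bool):
        super().__init__(message)
        self.collected = collected


class ChildError(EsiError):
    """A child interface failed; carries the name path down the call tree."""

    def __init__(self, path: str, original: BaseException):
        super().__init__(f"child '{path}' failed: {original}")
        self.path = path
        self.original = original

    @staticmethod
    def wrap(parent_name: str, child_name: str, exc: BaseException) -> "ChildError":
        if isinstance(exc, ChildError):
            return ChildError(f"{parent_name}/{exc.path}", exc.original)
        return ChildError(f"{parent_name}/{child_name}", exc)


class MappingError(EsiError):
    """Invalid QM/MM region map (out-of-range, overlapping, crossing bonds)."""


class DegeneracyError(EsiError):
    """Analytic derivative undefined because two states are (near-)degenerate."""


class ConditioningError(EsiError):
    """Branching-plane vectors (nearly) parallel; projected step ill-defined."""


class ComparisonError(EsiError):
    """Committee results have mismatched shapes or attributes."""


class DeviationError(EsiError):
    """Committee disagreement above threshold (intentional control flow).

    ``details`` maps attribute name -> measured deviation value.
    """

    def __init__(self, details: dict):
        msg = ", ".join(f"{k}={v:.6g}" for k, v in details.items())
        super().__init__(f"committee deviation exceeded threshold: {msg}")
        self.details = dict(details)


class TrajectoryTermination(EsiError):
    """Signal (not an error) that the caller should stop the trajectory."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class StorageError(EsiError):
    """Database store unwritable/unreadable."""
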