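"""State-space bookkeeping over spin multiplets.

The electronic state space is declared as a number of states per spin
multiplicity (index m of the list corresponds to multiplicity m+1).  Every
spin sublevel (Ms component) is carried explicitly, so a triplet contributes
three sublevels that duplicate all spin-independent data.  The canonical
sublevel ordering used by every tensor in the package is:

    ascending multiplicity, then state index within the multiplicity,
    then ascending Ms.

Example: ``states_per_mult = [4, 0, 3]`` (4 singlets, 3 triplets) yields
``4 + 3*3 = 13`` sublevels.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidMoleculeError

__all__ = ["Sublevel", "count_total_states", "build_state_map", "model_state_index"]


@dataclass(frozen=True)
class Sublevel:
    """One spin sublevel: (multiplicity, 1-based state index within it, Ms)."""

    mult: int
    state: int
    ms: float

    def __iter__(self):
        return iter((self.mult, self.state, self.ms))


def _validate(states_per_mult) -> list[int]:
    states = list(states_per_mult)
    if not states or any((not float(n).is_integer()) or n < 0 for n in states):
        raise InvalidMoleculeError(
            f"states per multiplicity must be non-negative integers, got {states!r}"
        )
    if all(n == 0 for n in states):
        raise InvalidMoleculeError("at least one state must be requested")
    return [int(n) for n in states]


def count_total_states(states_per_mult) -> int:
    """Total sublevel count: sum over multiplicities of n_states * multiplicity."""
    states = _validate(states_per_mult)
    return sum(n * (m + 1) for m, n in enumerate(states))


def build_state_map(states_per_mult) -> list[Sublevel]:
    """Enumerate all sublevels in the canonical ordering.

    Ms runs from -S to +S in integer steps with S = (mult - 1) / 2, so a
    doublet carries Ms = -1/2, +1/2 and a triplet Ms = -1, 0, +1.
    """
    states = _validate(states_per_mult)
    out: list[Sublevel] = []
    for m, n in enumerate(states):
        mult = m + 1
        spin = (mult - 1) / 2.0
        for istate in range(1, n + 1):
            for k in range(mult):
                out.append(Sublevel(mult, istate, -spin + k))
    return out


def model_state_index(states_per_mult) -> list[int]:
    """Map each sublevel to its spin-free ("model") state index.

    Spin-free states are numbered 0..n_model-1 in the same mult-then-state
    order; all Ms components of one multiplet share an index.  This is the
    duplication map used when a backend computes only spin-free quantities.
    """
    states = _validate(states_per_mult)
    out: list[int] = []
    base = 0
    for m, n in enumerate(states):
        mult = m + 1
        for istate in range(n):
            out.extend([base + istate] * mult)
        base += n
    return out
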