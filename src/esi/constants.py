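"""Physical constants and unit helpers.

All internal quantities are in Hartree atomic units (energies in Hartree,
lengths in Bohr, dipoles in e*Bohr).  Conversions happen only at the file
boundary (xyz files in Angstrom) and at presentation time (meV displays).
Constants follow CODATA 2018.
"""

from __future__ import annotations

#: One Hartree in electron volts (CODATA 2018).
HARTREE_TO_EV = 27.211386245988

#: One Hartree in milli-electron volts.
HARTREE_TO_MEV = HARTREE_TO_EV * 1000.0

#: One Bohr in Angstrom (CODATA 2018).
BOHR_TO_ANGSTROM = 0.529177210903

ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM


def hartree_to_mev(x: float) -> float:
    """Convert an energy from Hartree to meV (no rounding)."""
    return x * HARTREE_TO_MEV


def format_mev(x_hartree: float) -> str:
    """Format an energy (Hartree) in meV for display.

    Small values (below 20 meV: excited-state gaps) are shown with one
    decimal, larger values (e.g. ML error thresholds) to the nearest
    integer.
    """
    mev = hartree_to_mev(x_hartree)
    if abs(mev) < 20.0:
        return f"{mev:.1f}"
    return f"{round(mev):d}"


def format_percent(p: float) -> str:
    """Format a fraction in [0, 1] as a whole percent (e.g. 0.758 -> '76')."""
    return f"{round(p * 100.0):d}"
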