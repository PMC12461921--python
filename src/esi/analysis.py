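"""Trajectory-ensemble analysis: classical populations and confidence bands.

For a swarm of surface-hopping trajectories, the classical population of
state k at a time step is the fraction of trajectories whose active state
is k.  The 95% confidence band on such a binomial fraction P over N
trajectories is the normal approximation

    P +/- 1.96 * sqrt(P (1 - P) / N).
"""

from __future__ import annotations

import numpy as np

from .errors import EsiError

__all__ = ["classical_populations", "ci_halfwidth"]

#: Standard-normal quantile for a two-sided 95% confidence level.
Z_95 = 1.96


def classical_populations(active_state_series, n_states: int) -> np.ndarray:
    """Per-step population fractions from active-state time series.

    ``active_state_series`` is an (n_traj, n_steps) array of 1-based active
    state indices (one row per trajectory, all rows equal length).  Returns
    an (n_steps, n_states) array whose rows sum to one.
    """
    series = np.asarray(active_state_series, dtype=int)
    if series.ndim != 2:
        raise EsiError("active-state series must be a 2D (n_traj, n_steps) array")
    if series.min() < 1 or series.max() > n_states:
        raise EsiError(
            f"active state indices must lie in 1..{n_states}, found "
            f"[{series.min()}, {series.max()}]"
        )
    n_traj, n_steps = series.shape
    pops = np.zeros((n_steps, n_states))
    for k in range(1, n_states + 1):
        pops[:, k - 1] = np.sum(series == k, axis=0) / n_traj
    return pops


def ci_halfwidth(p: float, n: int) -> float:
    """95% confidence half-width of a binomial fraction: 1.96*sqrt(P(1-P)/N)."""
    if not 0.0 <= p <= 1.0:
        raise EsiError(f"population fraction must be in [0, 1], got {p}")
    if n < 1:
        raise EsiError("trajectory count must be positive")
    return Z_95 * float(np.sqrt(p * (1.0 - p) / n))
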