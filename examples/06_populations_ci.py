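"""Classical populations of a trajectory swarm with 95% confidence bands.

Simulates active-state series for 50 trajectories decaying from the second
excited state and prints per-step populations with the binomial confidence
half-width P +/- 1.96*sqrt(P(1-P)/N).
"""

import numpy as np

import esi

rng = np.random.default_rng(5)
n_traj, n_steps = 50, 12
series = np.full((n_traj, n_steps), 2, dtype=int)
for t in range(n_traj):
    hop = rng.integers(1, n_steps)        # stochastic decay step
    series[t, hop:] = 1

pops = esi.classical_populations(series, n_states=2)
print("step   P(S1)  P(S2)   +/- (95% CI)")
for step, (p1, p2) in enumerate(pops):
    hw = esi.ci_halfwidth(p1, n_traj)
    print(f"{step:4d}  {p1:.3f}  {p2:.3f}   {hw:.3f}")

final = pops[-1, 0]
hw = esi.ci_halfwidth(final, n_traj)
print(f"\nfinal S1 population: {esi.constants.format_percent(final)} +/- "
      f"{esi.constants.format_percent(hw)} %")
# With only 50 trajectories the half-width is around ten percentage points;
# it shrinks with 1/sqrt(N) as more trajectories are added.
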