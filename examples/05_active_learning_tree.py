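"""Active-learning interface tree: fallback over a committee and a recorder.

The trial branch is an adaptive-sampling committee (leader + advisor; the
advisor carries a planted disagreement bump in one region of geometry
space).  When the committee deviates beyond 0.8 mEh on the energies, the
fallback parent calls the backup branch — a database recorder around the
reference model — so exactly the disputed geometries are recorded as new
training points.  Two consecutive committee failures terminate the run.
"""

import numpy as np

import esi
from esi.containers import RequestSet
from esi.harness import build_tree, run_sequence

rng = np.random.default_rng(11)
leader = esi.random_model(rng, n_states=3)
bad_region = leader.r0 + 0.8
advisor = esi.with_bump(leader, 0.01, bad_region, 0.3)

tree = {
    "interface": "fallback",
    "template": {"max_consecutive_failures": 2},
    "children": {
        "trial": {
            "interface": "adaptive",
            "template": {"threshold": ("energies", 0.0008)},  # 0.8 mEh = 22 meV
            "children": {
                "leader": {"interface": "lvc_model",
                           "template": {"model_object": leader}},
                "advisor": {"interface": "lvc_model",
                            "template": {"model_object": advisor}},
            },
        },
        "backup": {
            "interface": "database",
            "children": {
                "child": {"interface": "lvc_model",
                          "template": {"model_object": leader}},
            },
        },
    },
}

geoms = [
    bad_region.reshape(-1, 3) if step in (10, 25, 48, 49)
    else (leader.r0 + 0.001 * step).reshape(-1, 3)
    for step in range(50)
]
root = build_tree(tree, esi.model_molecule(leader))
results, stop = run_sequence(root, geoms,
                             RequestSet(hamiltonian=True, gradients="all"))

print(f"completed steps : {len(results)} of {len(geoms)}")
print(f"stop reason     : {stop}")
print(f"fallback events : {[s for s, kind in root.events if kind == 'backup']}")
print(f"database records: {[r['step'] for r in root.children['backup'].store.read()]}")
# Steps 10 and 25 are isolated disagreements (fallback, then recovery);
# steps 48+49 are consecutive, so the trajectory aborts at step 49 and the
# database holds reference results for exactly the disputed geometries.
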