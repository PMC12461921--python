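"""Shared fixtures: model factories and call-tree builders."""

import numpy as np
import pytest

import esi
from esi.containers import RequestSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_lvc_interface(model, states_per_mult=None, template_extra=None, name="lvc"):
    """Fully initialized analytic-model interface."""
    iface = esi.LVCModelInterface(name=name)
    iface.setup_molecule(esi.model_molecule(model, states_per_mult))
    tpl = {"model_object": model}
    tpl.update(template_extra or {})
    iface.read_template(tpl)
    iface.read_resources(None)
    iface.finalize()
    return iface


def make_numdiff(model, delta=1e-3, scheme="diabatic", child_extra=None,
                 properties="grad nacdr", phase_fix=True, states_per_mult=None):
    """Numerical-differentiation hybrid over one analytic-model child."""
    nd = esi.NumDiffInterface(name="numdiff")
    child = esi.LVCModelInterface(name="ref")
    tpl = {"model_object": model}
    tpl.update(child_extra or {})
    child._pending_template = tpl
    nd.add_child("ref", child)
    nd.setup_molecule(esi.model_molecule(model, states_per_mult))
    nd.read_template(
        {"delta": delta, "scheme": scheme, "properties": properties,
         "phase_fix": phase_fix}
    )
    nd.read_resources(None)
    nd.finalize()
    return nd


def full_request(step=0, nac=True, dm=False):
    return RequestSet(
        hamiltonian=True, gradients="all", nac_vectors=nac, dipoles=dm, step=step
    )


def translation_invariant_model(rng, n_states=2):
    """Two-atom diabatic model depending only on the interatomic vector."""
    nd = 6
    diff = np.zeros((nd, nd))
    for k in range(3):
        v = np.zeros(nd)
        v[k], v[3 + k] = 1.0, -1.0
        diff += np.outer(v, v)
    r0 = rng.normal(0.0, 0.5, nd)
    eps = np.linspace(0.0, 0.3, n_states)
    kappa = np.zeros((n_states, nd))
    for i in range(n_states):
        c = rng.normal(0.0, 0.05, 3)
        kappa[i, :3], kappa[i, 3:] = c, -c
    mu = np.zeros((n_states, n_states, nd))
    c = rng.normal(0.0, 0.05, 3)
    mu[0, 1, :3], mu[0, 1, 3:] = c, -c
    mu[1, 0] = mu[0, 1]
    return esi.DiabaticModel(r0, 0.5 * diff, eps, kappa, mu=mu)
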