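"""Analytic diabatic/MM model backends against independent oracles."""

import numpy as np
import pytest

import esi
from esi.containers import RequestSet
from esi.errors import DegeneracyError, InvalidMoleculeError, MappingError
from esi.models import (
    eval_adiabatic,
    analytic_gradient,
    analytic_nac,
    overlaps,
    mm_evaluate,
    pointcharge_gradient,
    load_diabatic_model,
)
from conftest import make_lvc_interface


class TestAdiabaticDecomposition:
    def test_eigenvalues_match_characteristic_polynomial(self):
        # independent oracle: roots of det(W - E I) via numpy's polynomial solver
        for seed in range(25):
            rng = np.random.default_rng(seed)
            model = esi.random_model(rng, n_states=3)
            R = model.r0 + rng.normal(0, 0.2, model.n_dof)
            w = model.diabatic(R)
            e, c = eval_adiabatic(model, R)
            roots = np.sort(np.roots(np.poly(w)).real)
            np.testing.assert_allclose(e, roots, atol=1e-10)
            assert np.max(np.abs(w @ c - c @ np.diag(e))) <= 1e-10

    def test_single_state_closed_form(self, rng):
        model = esi.DiabaticModel(
            r0=np.zeros(3), k=np.diag([0.5, 0.5, 0.5]), epsilon=[0.1],
            kappa=[[0.2, 0.0, 0.0]],
        )
        R = np.array([0.4, -0.2, 0.1])
        e, c = eval_adiabatic(model, R)
        expected = 0.5 * 0.5 * R @ R + 0.1 + 0.2 * R[0]
        assert e[0] == pytest.approx(expected, abs=1e-14)
        np.testing.assert_array_equal(c, [[1.0]])

    def test_uncoupled_crossing_is_degenerate(self):
        model = esi.DiabaticModel(
            r0=np.zeros(3), k=0.5, epsilon=[0.0, 0.1],
            kappa=[[0.0, 0, 0], [-0.1, 0, 0]],
        )
        # diabats cross where 0.1 - 0.1*x = 0
        e, _ = eval_adiabatic(model, np.array([1.0, 0.0, 0.0]))
        assert abs(e[1] - e[0]) <= 1e-12


class TestDerivativeOracles:
    def test_gradient_matches_finite_difference(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            model = esi.random_model(rng, n_states=3)
            R = model.r0 + rng.normal(0, 0.1, model.n_dof)
            for i in range(3):
                g = analytic_gradient(model, R, i)
                fd = np.zeros_like(g)
                for d in range(model.n_dof):
                    rp, rm = R.copy(), R.copy()
                    rp[d] += 1e-5
                    rm[d] -= 1e-5
                    fd[d] = (
                        eval_adiabatic(model, rp)[0][i]
                        - eval_adiabatic(model, rm)[0][i]
                    ) / 2e-5
                np.testing.assert_allclose(g, fd, atol=1e-7)

    def test_one_state_harmonic_gradient_exact(self):
        model = esi.DiabaticModel(
            r0=np.ones(3), k=np.diag([0.3, 0.6, 0.9]), epsilon=[0.0],
            kappa=[[0.1, 0.2, 0.3]],
        )
        R = np.array([1.5, 0.5, 1.0])
        expected = model.k @ (R - model.r0) + model.kappa[0]
        np.testing.assert_allclose(analytic_gradient(model, R, 0), expected, atol=1e-14)

    def test_nac_matches_overlap_finite_difference(self):
        # Eq-2-style oracle: d_ij ~ (S(R, R+delta e) - S(R, R-delta e)) / 2 delta
        for seed in range(10):
            rng = np.random.default_rng(seed)
            model = esi.random_model(rng)
            R = model.r0 + rng.normal(0, 0.1, model.n_dof)
            nac = analytic_nac(model, R, 0, 1)
            fd = np.zeros_like(nac)
            for d in range(model.n_dof):
                rp, rm = R.copy(), R.copy()
                rp[d] += 1e-4
                rm[d] -= 1e-4
                fd[d] = (
                    overlaps(model, R, rp)[0, 1] - overlaps(model, R, rm)[0, 1]
                ) / 2e-4
            np.testing.assert_allclose(nac, fd, atol=1e-5)

    def test_nac_antisymmetry(self, rng):
        model = esi.random_model(rng)
        R = model.r0 + 0.1
        np.testing.assert_allclose(
            analytic_nac(model, R, 0, 1), -analytic_nac(model, R, 1, 0),
            rtol=0, atol=1e-14,
        )

    def test_uncoupled_states_have_zero_nac(self):
        model = esi.DiabaticModel(
            r0=np.zeros(3), k=0.5, epsilon=[0.0, 0.5], kappa=np.zeros((2, 3))
        )
        np.testing.assert_allclose(
            analytic_nac(model, np.array([0.3, 0.1, 0.0]), 0, 1), 0.0, atol=1e-14
        )

    def test_degeneracy_raises(self, rng):
        model, meci, pair = esi.planted_ci_model(rng)
        with pytest.raises(DegeneracyError):
            analytic_gradient(model, meci.ravel(), pair[0])
        with pytest.raises(DegeneracyError):
            analytic_nac(model, meci.ravel(), *pair)


class TestOverlaps:
    def test_identity_at_same_geometry(self, rng):
        model = esi.random_model(rng, n_states=3)
        R = model.r0 + 0.2
        np.testing.assert_allclose(overlaps(model, R, R), np.eye(3), atol=1e-12)

    def test_orthogonality_random_pairs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            model = esi.random_model(rng, n_states=3)
            ra = model.r0 + rng.normal(0, 0.3, model.n_dof)
            rb = model.r0 + rng.normal(0, 0.3, model.n_dof)
            s = overlaps(model, ra, rb)
            np.testing.assert_allclose(s.T @ s, np.eye(3), atol=1e-12)


class TestMMModel:
    def test_bond_at_equilibrium_is_zero(self):
        mm = esi.MMModel(2, [(0, 1, 0.5, 2.0)], [0.0, 0.0])
        e, g, charges = mm_evaluate(mm, [[0, 0, 0], [0, 0, 2.0]])
        assert e == 0.0
        np.testing.assert_allclose(g, 0.0, atol=1e-14)

    def test_gradient_matches_finite_difference(self, rng):
        mm = esi.MMModel(
            3, [(0, 1, 0.4, 2.0), (1, 2, 0.6, 1.8)], [0.3, -0.5, 0.2]
        )
        R = rng.normal(0, 1, (3, 3)) + np.arange(3)[:, None] * 2.0
        e, g = mm.evaluate(R)
        for a in range(3):
            for d in range(3):
                rp, rm = R.copy(), R.copy()
                rp[a, d] += 1e-6
                rm[a, d] -= 1e-6
                fd = (mm.evaluate(rp)[0] - mm.evaluate(rm)[0]) / 2e-6
                assert g[a, d] == pytest.approx(fd, abs=1e-8)

    def test_charges_returned_independent_of_geometry(self, rng):
        mm = esi.MMModel(2, [], [0.1, -0.1])
        _, _, c1 = mm_evaluate(mm, rng.normal(size=(2, 3)))
        _, _, c2 = mm_evaluate(mm, rng.normal(size=(2, 3)))
        np.testing.assert_array_equal(c1, c2)

    def test_restriction_rejects_crossing_bond(self):
        mm = esi.MMModel(3, [(0, 1, 0.5, 2.0)], [0.0, 0.0, 0.0])
        with pytest.raises(MappingError):
            mm.restrict([0, 2])


class TestPointChargeEmbedding:
    def test_stark_gradients_consistent_with_energy(self, rng):
        model = esi.random_model(rng)
        model.stark = rng.normal(0, 0.5, (2, 3))
        R = model.r0 + 0.1
        pc_pos = rng.normal(0, 1, (2, 3)) + 6.0
        pc_val = np.array([0.3, -0.4])
        for i in range(2):
            g = analytic_gradient(model, R, i, pc_pos, pc_val)
            gpc = pointcharge_gradient(model, R, i, pc_pos, pc_val)
            for d in range(model.n_dof):
                rp, rm = R.copy(), R.copy()
                rp[d] += 1e-6
                rm[d] -= 1e-6
                fd = (
                    eval_adiabatic(model, rp, pc_pos, pc_val)[0][i]
                    - eval_adiabatic(model, rm, pc_pos, pc_val)[0][i]
                ) / 2e-6
                assert g[d] == pytest.approx(fd, abs=1e-7)
            for q in range(2):
                for d in range(3):
                    pp, pm = pc_pos.copy(), pc_pos.copy()
                    pp[q, d] += 1e-6
                    pm[q, d] -= 1e-6
                    fd = (
                        eval_adiabatic(model, R, pp, pc_val)[0][i]
                        - eval_adiabatic(model, R, pm, pc_val)[0][i]
                    ) / 2e-6
                    assert gpc[q, d] == pytest.approx(fd, abs=1e-7)


class TestPlantedIntersection:
    @pytest.mark.parametrize("n_states", [2, 3])
    def test_planted_geometry_is_degenerate(self, n_states):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            model, meci, (lo, up) = esi.planted_ci_model(rng, n_states=n_states)
            e, _ = eval_adiabatic(model, meci.ravel())
            assert abs(e[up] - e[lo]) <= 1e-12
            if n_states == 3:
                assert e[lo] - e[0] > 0.1  # spectator state well below

    def test_seam_minimum_of_mean_energy(self, rng):
        # perturbing the MECI within the seam plane must not lower the mean energy
        model, meci, (lo, up) = esi.planted_ci_model(rng)
        x = meci.ravel()
        e0 = eval_adiabatic(model, x)[0]
        mean0 = 0.5 * (e0[lo] + e0[up])
        for d in range(2, model.n_dof):
            for s in (+1, -1):
                xp = x.copy()
                xp[d] += s * 1e-3
                e = eval_adiabatic(model, xp)[0]
                assert 0.5 * (e[lo] + e[up]) >= mean0 - 1e-12


class TestInterfaceExpansion:
    def test_sublevels_duplicate_spin_free_data(self, rng):
        # 1 singlet + 1 triplet driven by a 2-state model: 4 sublevels
        model = esi.random_model(rng, n_states=2)
        iface = make_lvc_interface(model, states_per_mult=[1, 0, 1])
        out = iface.single_point(
            model.r0 + 0.1, RequestSet(hamiltonian=True, gradients="all", step=0)
        )
        e = out.energies
        assert out.n_total == 4
        assert e[1] == e[2] == e[3]  # triplet sublevels share the energy
        np.testing.assert_array_equal(out.grad[1], out.grad[2])
        np.testing.assert_array_equal(out.grad[2], out.grad[3])

    def test_soc_block_couples_multiplicities(self, rng):
        model = esi.random_model(rng, n_states=2)
        model.soc = np.array([[0.0, 1e-3], [1e-3, 0.0]], complex)
        iface = make_lvc_interface(model, states_per_mult=[1, 0, 1])
        out = iface.single_point(model.r0, RequestSet(hamiltonian=True, step=0))
        assert out.h[0, 1] == pytest.approx(1e-3)
        out.check_hermitian()

    def test_model_state_count_must_match_molecule(self, rng):
        model = esi.random_model(rng, n_states=2)
        iface = esi.LVCModelInterface()
        iface.setup_molecule(esi.model_molecule(model, [3]))
        iface.read_template({"model_object": model})
        iface.read_resources(None)
        with pytest.raises(InvalidMoleculeError):
            iface.finalize()


class TestParameterFile:
    def test_yaml_round_trip(self, tmp_path, rng):
        path = tmp_path / "model.yaml"
        path.write_text(
            "r0: [0.0, 0.0, 0.0]\n"
            "k: 0.5\n"
            "epsilon: [0.0, 0.2]\n"
            "kappa: [[0.05, 0.0, 0.0], [-0.05, 0.0, 0.0]]\n"
            "lam: [[0.0, 0.02], [0.02, 0.0]]\n"
        )
        model = load_diabatic_model(path)
        assert model.n_states == 2
        e, _ = eval_adiabatic(model, np.zeros(3))
        # 2x2 closed form: mean +/- sqrt(half-gap^2 + coupling^2)
        expected = 0.1 - np.sqrt(0.1**2 + 0.02**2)
        assert e[0] == pytest.approx(expected, abs=1e-14)
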