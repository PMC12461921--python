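"""Overlap-based numerical differentiation against the analytic oracles."""

import numpy as np
import pytest

import esi
from esi.containers import RequestSet
from esi.numdiff import (
    NumDiffConfig,
    fix_overlap_phases,
    grad_adiabatic,
    grad_diabatic,
    make_displacements,
    matrix_derivative,
    nac_adiabatic,
    nac_diabatic,
)
from conftest import full_request, make_numdiff, translation_invariant_model


class TestDisplacements:
    def test_count_and_single_axis(self):
        disp = make_displacements(np.zeros((1, 3)), 0.01)
        assert len(disp) == 6
        np.testing.assert_allclose(
            disp.geometries[(0, "z", "+")], [[0.0, 0.0, 0.01]]
        )

    def test_each_geometry_differs_in_exactly_one_coordinate(self, rng):
        R = rng.normal(size=(3, 3))
        delta = 0.02
        disp = make_displacements(R, delta)
        assert len(disp) == 18
        for (a, d, sign), geom in disp:
            diff = geom - R
            nz = np.nonzero(diff)
            assert len(nz[0]) == 1
            assert abs(diff[nz][0]) == pytest.approx(delta)

    def test_positive_delta_required(self):
        with pytest.raises(ValueError):
            make_displacements(np.zeros((1, 3)), -0.01)
        with pytest.raises(ValueError):
            NumDiffConfig(delta=0.0)


class TestDifferenceFormulas:
    def test_symmetric_hamiltonians_give_zero_gradient(self):
        h = np.diag([1.0, 2.0])
        np.testing.assert_array_equal(grad_adiabatic(h, h, 0.01), [0.0, 0.0])

    def test_identical_overlaps_give_zero_nac(self):
        s = np.eye(3)
        np.testing.assert_array_equal(nac_adiabatic(s, s, 0.01), np.zeros((3, 3)))

    def test_diabatic_reduces_to_adiabatic_for_identity_overlap(self, rng):
        hp = np.diag(rng.normal(size=4))
        hm = np.diag(rng.normal(size=4))
        eye = np.eye(4)
        np.testing.assert_allclose(
            grad_diabatic(eye, hp, eye, hm, 0.01),
            grad_adiabatic(hp, hm, 0.01),
            atol=1e-15,
        )

    def test_near_degenerate_pairs_flagged_not_divided(self):
        h = np.diag([0.0, 1e-9])
        s = np.eye(2)
        gaps = np.array([[0.0, -1e-9], [1e-9, 0.0]])
        out, flagged = nac_diabatic(s, h, s, h, 0.01, gaps)
        assert (0, 1) in flagged and (1, 0) in flagged
        np.testing.assert_array_equal(out, np.zeros((2, 2)))

    def test_constant_matrix_zero_derivative(self):
        m = np.full((2, 2), 0.3)
        eye = np.eye(2)
        for scheme in ("adiabatic", "diabatic"):
            np.testing.assert_allclose(
                matrix_derivative(m, m, eye, eye, 0.01, scheme), 0.0, atol=1e-15
            )


class TestPhaseFixing:
    def test_negative_identity_fully_flipped(self):
        fixed, flips, warnings = fix_overlap_phases(-np.eye(3))
        np.testing.assert_array_equal(fixed, np.eye(3))
        np.testing.assert_array_equal(flips, -np.ones(3))
        assert warnings == []

    def test_identity_unchanged(self):
        fixed, flips, _ = fix_overlap_phases(np.eye(2))
        np.testing.assert_array_equal(fixed, np.eye(2))
        np.testing.assert_array_equal(flips, np.ones(2))

    def test_state_tracking_warning_for_small_diagonal(self):
        s = np.array([[0.3, 0.95], [0.95, -0.3]])
        _, _, warnings = fix_overlap_phases(s)
        assert len(warnings) == 2


class TestAssembledDerivatives:
    def test_gradients_and_nacs_match_analytic(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            model = esi.random_model(rng, n_states=3)
            R = model.r0 + rng.normal(0, 0.1, model.n_dof)
            for scheme in ("adiabatic", "diabatic"):
                nd = make_numdiff(model, delta=1e-4, scheme=scheme)
                out = nd.single_point(R.reshape(-1, 3), full_request())
                for i in range(3):
                    np.testing.assert_allclose(
                        out.grad[i].ravel(),
                        esi.analytic_gradient(model, R, i),
                        atol=1e-5,
                    )
                    for j in range(3):
                        if i != j:
                            np.testing.assert_allclose(
                                out.nacdr[i, j].ravel(),
                                esi.analytic_nac(model, R, i, j),
                                atol=1e-5,
                            )

    def test_nac_diagonal_vanishes(self, rng):
        # norm conservation: <psi_i | d psi_i> ~ 0
        model = esi.random_model(rng)
        nd = make_numdiff(model, delta=1e-4, scheme="adiabatic")
        out = nd.single_point(
            (model.r0 + 0.1).reshape(-1, 3), full_request()
        )
        for i in range(2):
            assert np.max(np.abs(out.nacdr[i, i])) <= 1e-6

    def test_second_order_convergence(self):
        # halving delta cuts the error by ~4 (central differences)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            model = esi.random_model(rng)
            R = model.r0 + 0.1
            ga = np.array([esi.analytic_gradient(model, R, i) for i in range(2)])
            na = esi.analytic_nac(model, R, 0, 1)
            errs_g, errs_n = [], []
            for delta in (1e-2, 5e-3):
                nd = make_numdiff(model, delta=delta, scheme="adiabatic")
                out = nd.single_point(R.reshape(-1, 3), full_request())
                errs_g.append(np.linalg.norm(out.grad.reshape(2, -1) - ga))
                errs_n.append(np.linalg.norm(out.nacdr[0, 1].ravel() - na))
            assert 0.2 <= errs_g[1] / errs_g[0] <= 0.3
            assert 0.2 <= errs_n[1] / errs_n[0] <= 0.3

    def test_schemes_agree_in_unmixed_limit(self, rng):
        # far from any crossing and at tiny delta, overlaps ~ identity
        model = esi.random_model(rng, coupling=0.01)
        R = model.r0 + 0.05
        outs = {}
        for scheme in ("adiabatic", "diabatic"):
            nd = make_numdiff(model, delta=1e-5, scheme=scheme)
            outs[scheme] = nd.single_point(R.reshape(-1, 3), full_request())
        np.testing.assert_allclose(
            outs["adiabatic"].grad, outs["diabatic"].grad, atol=1e-8
        )

    def test_diabatic_beats_adiabatic_near_intersection(self):
        # strong state mixing across +/-delta breaks direct differentiation
        for seed in range(3):
            rng = np.random.default_rng(seed)
            model, meci, _ = esi.planted_ci_model(rng)
            R = meci.ravel().copy()
            R[0] += 0.005
            R[1] += 0.002
            ga = np.array([esi.analytic_gradient(model, R, i) for i in range(2)])
            errs = {}
            for scheme in ("adiabatic", "diabatic"):
                nd = make_numdiff(model, delta=0.01, scheme=scheme)
                out = nd.single_point(R.reshape(-1, 3), full_request(nac=False))
                errs[scheme] = np.max(np.abs(out.grad.reshape(2, -1) - ga))
            assert errs["diabatic"] <= 1e-5
            assert errs["adiabatic"] > 100 * errs["diabatic"]

    def test_phase_flip_invariance(self, rng):
        model = esi.random_model(rng)
        R = (model.r0 + 0.1).reshape(-1, 3)
        plain = make_numdiff(model, scheme="diabatic").single_point(
            R, full_request()
        )
        flipped = make_numdiff(
            model, scheme="diabatic",
            child_extra={"overlap_phase_flip_seed": 1234},
        ).single_point(R, full_request())
        np.testing.assert_allclose(plain.grad, flipped.grad, atol=1e-12)
        np.testing.assert_allclose(plain.nacdr, flipped.nacdr, atol=1e-12)

    def test_translational_sum_rule(self, rng):
        model = translation_invariant_model(rng)
        R = model.r0 + rng.normal(0, 0.1, 6)
        nd = make_numdiff(model, delta=1e-3, scheme="diabatic")
        out = nd.single_point(R.reshape(2, 3), full_request())
        assert np.max(np.abs(out.grad.sum(axis=1))) <= 1e-8

    def test_dipole_derivative_recovers_linear_slope(self, rng):
        model = esi.random_model(rng, with_dipoles=True)
        R = model.r0 + 0.1
        nd = make_numdiff(model, delta=1e-3, scheme="diabatic",
                          properties="grad dmdr")
        req = RequestSet(hamiltonian=True, dipoles=True, dipole_derivatives=True,
                         step=0)
        out = nd.single_point(R.reshape(-1, 3), req)
        # the diabatized derivative removes state-rotation contributions:
        # its oracle is the model's dipole slope in the reference eigenbasis
        _, c_ref = esi.eval_adiabatic(model, R)
        slope = np.einsum("ai,pabd,bj->pijd", c_ref, model.dip1, c_ref)
        for d in range(model.n_dof):
            np.testing.assert_allclose(
                out.dmdr[:, :, :, d // 3, d % 3], slope[:, :, :, d], atol=1e-6
            )

    def test_adiabatic_matrix_derivative_matches_finite_difference(self, rng):
        model = esi.random_model(rng, with_dipoles=True)
        R = model.r0 + 0.1
        nd = make_numdiff(model, delta=1e-3, scheme="adiabatic",
                          properties="grad dmdr")
        req = RequestSet(hamiltonian=True, dipoles=True, dipole_derivatives=True,
                         step=0)
        out = nd.single_point(R.reshape(-1, 3), req)

        def dip(rv):
            _, c = esi.eval_adiabatic(model, rv)
            return np.einsum("ai,pab,bj->pij", c, model.dipole(rv), c)

        for d in range(model.n_dof):
            rp, rm = R.copy(), R.copy()
            rp[d] += 1e-6
            rm[d] -= 1e-6
            fd = (dip(rp) - dip(rm)) / 2e-6
            np.testing.assert_allclose(
                out.dmdr[:, :, :, d // 3, d % 3], fd, atol=1e-6
            )


class TestOrchestration:
    def test_grad_only_adiabatic_issues_no_overlap_calls(self, rng):
        model = esi.random_model(rng)
        nd = make_numdiff(model, scheme="adiabatic", properties="grad")
        req = RequestSet(hamiltonian=True, gradients="all", step=0)
        nd.single_point((model.r0 + 0.1).reshape(-1, 3), req)
        calls = sum(c.n_overlap_calls for c in nd.children.values())
        assert calls == 0

    def test_child_call_count_is_one_plus_six_per_atom(self, rng):
        model = esi.random_model(rng, n_atoms=2)
        nd = make_numdiff(model, scheme="diabatic")
        nd.single_point((model.r0 + 0.1).reshape(-1, 3), full_request())
        runs = {name: c._run_count for name, c in nd.children.items()}
        assert runs["ref"] == 1
        disp_counts = [v for k, v in runs.items() if k.startswith("disp")]
        assert disp_counts == [2] * 6  # each coordinate child reused for +/-
        assert 1 + sum(disp_counts) == 13

    def test_negotiation_requires_overlap_for_diabatic(self, rng):
        model = esi.random_model(rng)
        with pytest.raises(Exception) as err:
            make_numdiff(model, scheme="diabatic",
                         child_extra={"features": "h grad"})
        assert "overlap" in str(err.value)

    def test_derived_feature_set_extends_child(self, rng):
        model = esi.random_model(rng)
        nd = make_numdiff(model, scheme="adiabatic",
                          child_extra={"features": "h overlap"})
        feats = nd.get_features()
        assert {"grad", "nacdr"} <= set(feats)
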