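"""Committee deviation, fallback counting and database pass-through."""

import numpy as np
import pytest

import esi
from esi.containers import MoleculeSpec, QMout, RequestSet
from esi.errors import (
    ChildError,
    ComparisonError,
    DeviationError,
    TrajectoryTermination,
)
from esi.harness import build_tree, run_sequence
from esi.workflows import DeviationPolicy, RecordStore, deviation


def qmout_with_energies(energies):
    q = QMout(len(energies), 1)
    q.allocate(["h"])
    q.h[np.diag_indices(len(energies))] = energies
    return q


class TestDeviation:
    def test_identical_results_zero_deviation(self):
        q = qmout_with_energies([0.1, 0.2, 0.3])
        out = deviation(q, q.copy(), DeviationPolicy())
        assert out["energies"] == (0.0, False)

    def test_mae_threshold_exceeded(self):
        # 1 mHartree uniform energy error against the 0.8 mHartree threshold
        a = qmout_with_energies([0.1, 0.2, 0.3])
        b = qmout_with_energies([0.101, 0.201, 0.301])
        value, exceeded = deviation(a, b, DeviationPolicy())["energies"]
        assert value == pytest.approx(0.001)
        assert exceeded

    def test_mae_below_threshold(self):
        a = qmout_with_energies([0.1, 0.2, 0.3])
        b = qmout_with_energies([0.1006, 0.2006, 0.3006])
        value, exceeded = deviation(a, b, DeviationPolicy())["energies"]
        assert value == pytest.approx(0.0006)
        assert not exceeded

    def test_shape_mismatch_is_comparison_error(self):
        with pytest.raises(ComparisonError):
            deviation(
                qmout_with_energies([0.1]),
                qmout_with_energies([0.1, 0.2]),
                DeviationPolicy(),
            )

    @pytest.mark.parametrize(
        "metric, expected",
        [("mae", 0.003), ("rmsd", np.sqrt((0.001**2 + 0.005**2) / 2)), ("max", 0.005)],
    )
    def test_metric_variants(self, metric, expected):
        a = qmout_with_energies([0.0, 0.0])
        b = qmout_with_energies([0.001, -0.005])
        pol = DeviationPolicy({"energies": 0.01}, {"energies": metric})
        assert deviation(a, b, pol)["energies"][0] == pytest.approx(expected)

    def test_custom_metric_loaded_from_file(self, tmp_path):
        path = tmp_path / "metric.py"
        path.write_text(
            "import numpy as np\n"
            "def metric(a, b):\n"
            "    return float(np.median(np.abs(a - b)))\n"
        )
        pol = DeviationPolicy({"energies": 0.01}, {"energies": f"custom:{path}"})
        a = qmout_with_energies([0.0, 0.0, 0.0])
        b = qmout_with_energies([0.001, 0.002, 0.003])
        assert deviation(a, b, pol)["energies"][0] == pytest.approx(0.002)


def make_committee(leader_model, advisor_models, threshold=0.0008):
    children = {
        "leader": {"interface": "lvc_model", "template": {"model_object": leader_model}}
    }
    for k, adv in enumerate(advisor_models):
        name = "advisor" if k == 0 else f"advisor{k + 1}"
        children[name] = {"interface": "lvc_model", "template": {"model_object": adv}}
    cfg = {
        "interface": "adaptive",
        "template": {"threshold": ("energies", threshold)},
        "children": children,
    }
    return build_tree(cfg, esi.model_molecule(leader_model))


class TestAdaptiveSampling:
    def test_identical_models_pass_leader_through(self, rng):
        model = esi.random_model(rng)
        tree = make_committee(model, [model.copy()])
        out = tree.single_point(
            model.r0 + 0.1, RequestSet(hamiltonian=True, gradients="all", step=0)
        )
        direct = esi.eval_adiabatic(model, model.r0 + 0.1)[0]
        np.testing.assert_allclose(out.energies, direct, atol=1e-14)

    def test_perturbed_advisor_raises_with_details(self, rng):
        model = esi.random_model(rng)
        advisor = esi.with_bump(model, 0.01, model.r0 + 0.1, 0.5)
        tree = make_committee(model, [advisor])
        with pytest.raises(DeviationError) as err:
            tree.single_point(model.r0 + 0.1, RequestSet(hamiltonian=True, step=0))
        assert any("energies" in key for key in err.value.details)
        assert all(v > 0.0008 for v in err.value.details.values())

    def test_any_advisor_exceeding_triggers(self, rng):
        model = esi.random_model(rng)
        good = model.copy()
        bad = esi.with_bump(model, 0.01, model.r0 + 0.1, 0.5)
        tree = make_committee(model, [good, bad])
        with pytest.raises(DeviationError) as err:
            tree.single_point(model.r0 + 0.1, RequestSet(hamiltonian=True, step=0))
        assert any(key.startswith("advisor2") for key in err.value.details)


class TestFallback:
    def _tree(self, leader, advisor, backup, max_failures=2):
        cfg = {
            "interface": "fallback",
            "template": {"max_consecutive_failures": max_failures},
            "children": {
                "trial": {
                    "interface": "adaptive",
                    "template": {"threshold": ("energies", 0.0008)},
                    "children": {
                        "leader": {"interface": "lvc_model",
                                   "template": {"model_object": leader}},
                        "advisor": {"interface": "lvc_model",
                                    "template": {"model_object": advisor}},
                    },
                },
                "backup": {"interface": "lvc_model",
                           "template": {"model_object": backup}},
            },
        }
        return build_tree(cfg, esi.model_molecule(leader))

    def test_trial_success_passes_through_and_resets(self, rng):
        model = esi.random_model(rng)
        tree = self._tree(model, model.copy(), model.copy())
        out = tree.single_point(model.r0, RequestSet(hamiltonian=True, step=0))
        np.testing.assert_allclose(
            out.energies, esi.eval_adiabatic(model, model.r0)[0], atol=1e-14
        )
        assert tree.consecutive_failures == 0
        assert tree.events == [(0, "trial")]

    def test_nonconsecutive_failures_never_terminate(self, rng):
        model = esi.random_model(rng)
        bad_center = model.r0 + 1.0
        advisor = esi.with_bump(model, 0.01, bad_center, 0.2)
        tree = self._tree(model, advisor, model.copy(), max_failures=2)
        geoms = [bad_center, model.r0, bad_center]  # fail, ok, fail
        req = RequestSet(hamiltonian=True)
        results, stop = run_sequence(tree, [g.reshape(-1, 3) for g in geoms], req)
        assert stop is None
        assert len(results) == 3
        assert [kind for _, kind in tree.events] == ["backup", "trial", "backup"]

    def test_two_consecutive_failures_terminate(self, rng):
        model = esi.random_model(rng)
        bad_center = model.r0 + 1.0
        advisor = esi.with_bump(model, 0.01, bad_center, 0.2)
        tree = self._tree(model, advisor, model.copy(), max_failures=2)
        geoms = [model.r0, bad_center, bad_center]
        results, stop = run_sequence(
            tree, [g.reshape(-1, 3) for g in geoms], RequestSet(hamiltonian=True)
        )
        assert len(results) == 2  # step 2's termination yields no result
        assert stop is not None and "2 consecutive" in stop

    def test_backup_failure_is_fatal(self, rng, monkeypatch):
        model = esi.random_model(rng)
        advisor = esi.with_bump(model, 0.01, model.r0, 0.5)
        tree = self._tree(model, advisor, model.copy())
        monkeypatch.setattr(
            tree.children["backup"], "_execute",
            lambda: (_ for _ in ()).throw(RuntimeError("synthetic backup crash")),
        )
        with pytest.raises(ChildError) as err:
            tree.single_point(model.r0, RequestSet(hamiltonian=True, step=0))
        assert err.value.path.endswith("backup")


class TestDatabase:
    def _tree(self, model, db_path=None):
        cfg = {
            "interface": "database",
            "template": {"db_path": str(db_path)} if db_path else {},
            "children": {
                "child": {"interface": "lvc_model",
                          "template": {"model_object": model}}
            },
        }
        return build_tree(cfg, esi.model_molecule(model))

    def test_record_round_trip(self, rng, tmp_path):
        model = esi.random_model(rng)
        tree = self._tree(model, tmp_path / "db.jsonl")
        R = (model.r0 + 0.1).reshape(-1, 3)
        out = tree.single_point(
            R, RequestSet(hamiltonian=True, gradients="all", step=0)
        )
        records = tree.store.read()
        assert len(records) == 1
        np.testing.assert_allclose(records[0]["geometry"], R, atol=1e-12)
        stored_h = RecordStore._decode(records[0]["tensors"]["h"])
        np.testing.assert_allclose(stored_h, out.h, atol=1e-12)

    def test_pass_through_transparency(self, rng):
        # wrapping in a database changes no numerical result
        model = esi.random_model(rng)
        tree = self._tree(model)
        bare = esi.LVCModelInterface()
        bare.setup_molecule(esi.model_molecule(model))
        bare.read_template({"model_object": model})
        bare.read_resources(None)
        bare.finalize()
        req = RequestSet(hamiltonian=True, gradients="all", nac_vectors=True, step=0)
        R = (model.r0 + 0.2).reshape(-1, 3)
        wrapped = tree.single_point(R, req)
        direct = bare.single_point(R, req)
        for name in ("h", "grad", "nacdr"):
            np.testing.assert_array_equal(
                getattr(wrapped, name), getattr(direct, name)
            )

    def test_one_record_per_run(self, rng):
        model = esi.random_model(rng)
        tree = self._tree(model)
        for step in range(4):
            tree.single_point(
                (model.r0 + 0.01 * step).reshape(-1, 3),
                RequestSet(hamiltonian=True, step=step),
            )
        assert len(tree.store) == 4
        assert [r["step"] for r in tree.store.read()] == [0, 1, 2, 3]


class TestFullWorkflowTree:
    def test_rehearsal_records_only_fallback_steps(self, rng):
        """Fallback over [committee | database->model]: the database collects
        exactly the backup-path (reference) calculations."""
        leader = esi.random_model(rng, n_states=3)
        bad_center = leader.r0 + 0.8
        advisor = esi.with_bump(leader, 0.01, bad_center, 0.3)
        cfg = {
            "interface": "fallback",
            "template": {"max_consecutive_failures": 2},
            "children": {
                "trial": {
                    "interface": "adaptive",
                    "template": {"threshold": ("energies", 0.0008)},
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
                                  "template": {"model_object": leader}}
                    },
                },
            },
        }
        mol = esi.model_molecule(leader)
        disagree_steps = (5, 12, 19)
        geoms = [
            bad_center.reshape(-1, 3)
            if step in disagree_steps
            else (leader.r0 + 0.005 * step).reshape(-1, 3)
            for step in range(25)
        ]
        root = build_tree(cfg, mol)
        results, stop = run_sequence(
            root, geoms, RequestSet(hamiltonian=True, gradients="all")
        )
        assert stop is None and len(results) == 25
        db_steps = [r["step"] for r in root.children["backup"].store.read()]
        assert db_steps == list(disagree_steps)
        # determinism: an identical rerun reproduces the same event sequence
        root2 = build_tree(cfg, mol)
        run_sequence(root2, geoms, RequestSet(hamiltonian=True, gradients="all"))
        assert root2.events == root.events
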