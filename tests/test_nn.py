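"""Descriptor invariances, NN training behaviour and analytic forces."""

import numpy as np
import pytest

from photodyn.core import Geometry
from photodyn.errors import InvalidInputError
from photodyn.io import Dataset
from photodyn.nn import (Hyperparams, NNModel, TrainingSet, descriptor,
                         descriptor_jacobian, random_grid_search, train)

from conftest import diatomic_scan


def _rotation(angle, axis=2):
    c, s = np.cos(angle), np.sin(angle)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = R[j, j] = c
    R[i, j], R[j, i] = -s, s
    return R


def _triatomic(coords):
    return Geometry(("X", "X", "X"), coords, np.ones(3))


class TestDescriptor:
    def test_collinear_values_in_pair_order(self):
        g = _triatomic(np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]]))
        np.testing.assert_allclose(descriptor(g), [1.0, 1 / 3, 1 / 2])

    def test_rigid_rotation_invariance(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.3, 2.0, 0.4]])
        g = _triatomic(coords)
        g_rot = _triatomic(coords @ _rotation(0.7).T @ _rotation(1.1, 0).T)
        np.testing.assert_allclose(descriptor(g), descriptor(g_rot), atol=1e-12)

    def test_translation_invariance(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.3, 2.0, 0.4]])
        g = _triatomic(coords)
        g_t = _triatomic(coords + np.array([10.0, -3.0, 0.5]))
        np.testing.assert_allclose(descriptor(g), descriptor(g_t), atol=1e-14)

    def test_jacobian_matches_finite_differences(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.3, 2.0, 0.4]])
        g = _triatomic(coords)
        jac = descriptor_jacobian(g)
        h = 1e-6
        for a in range(3):
            for x in range(3):
                cp, cm = coords.copy(), coords.copy()
                cp[a, x] += h
                cm[a, x] -= h
                fd = (descriptor(_triatomic(cp)) - descriptor(_triatomic(cm))) / (2 * h)
                np.testing.assert_allclose(jac[:, a, x], fd, atol=1e-8)

    def test_coincident_atoms_rejected(self):
        g = _triatomic(np.array([[0.0, 0, 0], [1e-5, 0, 0], [2.0, 0, 0]]))
        with pytest.raises(InvalidInputError):
            descriptor(g)


class TestPrediction:
    def test_deterministic_and_invariant(self, ac_nn, ac_model):
        g = ac_model.reference_geometry()
        a = ac_nn.predict(g)
        b = ac_nn.predict(g)
        np.testing.assert_array_equal(a.energies, b.energies)
        shifted = g.with_coords(g.coords + np.array([3.0, -1.0, 2.0]))
        c = ac_nn.predict(shifted)
        np.testing.assert_allclose(a.energies, c.energies, atol=1e-12)

    def test_matches_reference_within_training_rmse(self, ac_nn, ac_dataset):
        worst = 0.0
        for rec in ac_dataset.records[::6]:
            pred = ac_nn.predict(rec.geometry)
            worst = max(worst, np.abs(pred.energies - rec.properties.energies).max())
        assert worst < 5 * max(ac_nn.train_rmse["energy"], 1e-4)

    def test_forces_match_finite_differences(self, ac_nn, ac_model):
        g = diatomic_scan(ac_model, [2.7])[0]
        grads = ac_nn.analytic_forces(g)
        h = 1e-5
        for a in range(2):
            for x in range(3):
                cp, cm = g.coords.copy(), g.coords.copy()
                cp[a, x] += h
                cm[a, x] -= h
                fd = (ac_nn.predict(g.with_coords(cp)).energies
                      - ac_nn.predict(g.with_coords(cm)).energies) / (2 * h)
                np.testing.assert_allclose(grads[:, a, x], fd, rtol=1e-5,
                                           atol=1e-9)

    def test_net_force_and_torque_vanish(self, ci_nn, ci_model):
        g = ci_model.reference_geometry()
        grads = ci_nn.analytic_forces(g)
        for state in range(2):
            f = -grads[state]
            assert np.abs(f.sum(axis=0)).max() < 1e-10
            torque = np.cross(g.coords - g.coords.mean(axis=0), f).sum(axis=0)
            assert np.abs(torque).max() < 1e-10

    def test_forces_are_conservative_on_a_loop(self, ac_nn, ac_model):
        """Work integrated around a closed loop vanishes (exact gradient
        field of the predicted energy)."""
        base = diatomic_scan(ac_model, [2.5])[0]
        thetas = np.linspace(0, 2 * np.pi, 200, endpoint=True)
        loop = [base.coords + 0.05 * np.array([[0, 0, 0],
                                               [np.cos(t), np.sin(t), 0]])
                for t in thetas]
        work = 0.0
        for a, b in zip(loop[:-1], loop[1:]):
            mid = base.with_coords(0.5 * (a + b))
            f = -ac_nn.analytic_forces(mid)[0]
            work += np.sum(f * (b - a))
        assert abs(work) < 1e-8

    def test_save_load_round_trip(self, ac_nn, ac_model, tmp_path):
        path = tmp_path / "model.npz"
        ac_nn.save(path)
        clone = NNModel.load(path)
        g = diatomic_scan(ac_model, [3.1])[0]
        np.testing.assert_array_equal(clone.predict(g).energies,
                                      ac_nn.predict(g).energies)
        np.testing.assert_array_equal(clone.predict(g).nacs,
                                      ac_nn.predict(g).nacs)
        assert clone.val_rmse == pytest.approx(ac_nn.val_rmse)


class TestTraining:
    def test_small_dataset_is_memorized(self, ac_model):
        geoms = diatomic_scan(ac_model, np.linspace(2.2, 3.4, 12))
        ds = Dataset.from_provider(ac_model, geoms)
        ts = TrainingSet(ds, np.array([0, 1, 2, 3, 4, 7, 8, 9, 10, 11]),
                         np.array([5, 6]))
        model = train(ts, Hyperparams(hidden=(80, 80), epochs=10000,
                                      patience=10 ** 6,
                                      learning_rate=2e-3), seed=0)
        assert model.train_rmse["energy"] < 1e-4

    def test_same_seed_reproduces_training(self, ac_dataset):
        ts = TrainingSet.random_split(ac_dataset, 0.15, seed=3)
        hp = Hyperparams(epochs=300)
        a = train(ts, hp, seed=5)
        b = train(ts, hp, seed=5)
        assert a.val_rmse == b.val_rmse

    def test_force_loss_improves_gradient_accuracy(self, ac_dataset):
        """Training through the analytic derivative (force weight > 0)
        lowers held-out gradient RMSE versus energies-only training."""
        ts = TrainingSet.random_split(ac_dataset, 0.15, seed=3)
        hp0 = Hyperparams(epochs=1500,
                          loss_weights={"energy": 1.0, "force": 0.0,
                                        "nac": 0.1, "dipole": 0.1, "soc": 0.1})
        hp1 = hp0.replace(loss_weights={"energy": 1.0, "force": 1.0,
                                        "nac": 0.1, "dipole": 0.1, "soc": 0.1})
        without = train(ts, hp0, seed=4)
        with_force = train(ts, hp1, seed=4)
        assert with_force.val_rmse["force"] < without.val_rmse["force"]

    def test_validation_error_shrinks_with_training_set_size(self, ac_model):
        rng_sizes = [10, 30, 90]
        rmses = []
        for n in rng_sizes:
            geoms = diatomic_scan(ac_model, np.linspace(1.8, 4.4, n))
            ds = Dataset.from_provider(ac_model, geoms)
            val = []
            for seed in range(2):
                ts = TrainingSet.random_split(ds, 0.2, seed=seed)
                val.append(train(ts, Hyperparams(epochs=1200),
                                 seed=seed).val_rmse["energy"])
            rmses.append(np.mean(val))
        assert rmses[2] < rmses[0]


class TestGridSearch:
    def test_single_trial_returns_it(self, ac_dataset):
        ts = TrainingSet.random_split(ac_dataset, 0.15, seed=0)
        hp, table = random_grid_search(ts, {"epochs": [200]}, 1, seed=0)
        assert hp.epochs == 200
        assert len(table) == 1

    def test_good_architecture_beats_degenerate(self, ac_dataset):
        ts = TrainingSet.random_split(ac_dataset, 0.15, seed=0)
        space = {"hidden": [(1,), (50, 50)]}
        hp, table = random_grid_search(ts, space, 6, seed=1)
        assert hp.hidden == (50, 50)

    def test_same_seed_same_trial_sequence(self, ac_dataset):
        ts = TrainingSet.random_split(ac_dataset, 0.15, seed=0)
        space = {"epochs": [100, 200], "learning_rate": [1e-3, 5e-3]}
        _, t1 = random_grid_search(ts, space, 4, seed=9)
        _, t2 = random_grid_search(ts, space, 4, seed=9)
        assert t1.equals(t2)

    def test_empty_space_rejected(self, ac_dataset):
        ts = TrainingSet.random_split(ac_dataset, 0.15, seed=0)
        with pytest.raises(InvalidInputError):
            random_grid_search(ts, {}, 3)
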