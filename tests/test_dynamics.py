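"""Surface-hopping dynamics: initialization, propagation, hopping and
energy bookkeeping."""

import numpy as np
import pytest

from photodyn.core import Geometry
from photodyn.dynamics import (attempt_hop, electronic_step,
                               hop_probabilities, initialize,
                               rescale_velocity, run_ensemble_of_trajectories,
                               run_trajectory)
from photodyn.errors import InvalidInputError
from photodyn.models import AvoidedCrossingModel
from photodyn.sampling import compute_hessian
from photodyn.units import AU_PER_FS, ME_PER_AMU


class TestInitialize:
    def test_fixed_spec_is_deterministic(self, decay_model):
        g = decay_model.reference_geometry()
        st = initialize(g, {"kind": "fixed", "n_states": 3}, 2, seed=0)
        np.testing.assert_array_equal(st.geometry.coords, g.coords)
        np.testing.assert_array_equal(st.velocities, 0.0)
        np.testing.assert_array_equal(st.coefficients, [0, 0, 1])
        assert st.active == 2

    def test_wigner_width_matches_harmonic_ground_state(self, ac_model):
        """Position variance along the vibrational mode equals
        hbar/(2 mu omega) for the harmonic ground-state Wigner function."""
        g = ac_model.reference_geometry()
        hess = compute_hessian(ac_model, g, state=0)
        spec = {"kind": "wigner", "hessian": hess, "n_states": 2}
        bonds = []
        for k in range(10_000):
            st = initialize(g, spec, 0, seed=k)
            bonds.append(np.linalg.norm(st.geometry.coords[0]
                                        - st.geometry.coords[1]))
        mu = 0.5 * ac_model.masses[0] * ME_PER_AMU
        omega = np.sqrt(ac_model.k1 / mu)
        expected = 1.0 / (2 * mu * omega)
        assert np.var(bonds) == pytest.approx(expected, rel=0.05)

    def test_same_seed_same_conditions(self, ac_model):
        g = ac_model.reference_geometry()
        hess = compute_hessian(ac_model, g, state=0)
        spec = {"kind": "wigner", "hessian": hess, "n_states": 2}
        a = initialize(g, spec, 1, seed=42)
        b = initialize(g, spec, 1, seed=42)
        np.testing.assert_array_equal(a.geometry.coords, b.geometry.coords)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_invalid_spec_rejected(self, ac_model):
        with pytest.raises(InvalidInputError):
            initialize(ac_model.reference_geometry(), {"kind": "maxwell"}, 0)


class _FlatSurface:
    """Zero-force single-surface source for free-motion checks."""

    n_states = 2

    def evaluate(self, geom):
        from photodyn.core import ElectronicProperties
        return ElectronicProperties(
            energies=np.array([0.0, 1.0]),
            gradients=np.zeros((2, geom.n_atoms, 3)),
            nacs=np.zeros((1, geom.n_atoms, 3)))


class TestNuclearPropagation:
    def test_zero_force_gives_uniform_motion(self):
        g = Geometry(("X", "X"), np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                     np.ones(2))
        st = initialize(g, {"kind": "fixed", "n_states": 2}, 0, seed=0)
        v0 = np.array([[0.001, 0, 0], [0.0, 0, 0]])
        st.velocities = v0.copy()
        traj = run_trajectory(st, _FlatSurface(), dt_fs=0.5, t_max_fs=10.0)
        t_au = traj.times_fs[-1] * AU_PER_FS
        np.testing.assert_allclose(traj.positions[-1][0, 0],
                                   v0[0, 0] * t_au, atol=1e-12)

    def test_harmonic_period(self):
        """Oscillation period on an uncoupled harmonic well matches
        2 pi / omega."""
        model = AvoidedCrossingModel(coupling=0.0)
        mu = 0.5 * model.masses[0] * ME_PER_AMU
        omega = np.sqrt(model.k1 / mu)
        period_fs = 2 * np.pi / omega / AU_PER_FS
        ac_model = model
        g = ac_model.make_geometry(np.array([[0.0, 0, 0], [2.05, 0, 0]]))
        st = initialize(g, {"kind": "fixed", "n_states": 2}, 0, seed=0)
        traj = run_trajectory(st, ac_model, dt_fs=period_fs / 1000,
                              t_max_fs=2.2 * period_fs)
        bond = np.linalg.norm(traj.positions[:, 0] - traj.positions[:, 1],
                              axis=1)
        # period from successive minima of the bond length
        minima = [k for k in range(1, len(bond) - 1)
                  if bond[k] < bond[k - 1] and bond[k] <= bond[k + 1]]
        measured = (traj.times_fs[minima[1]] - traj.times_fs[minima[0]])
        assert measured == pytest.approx(period_fs, rel=1e-3)

    def test_energy_drift_scales_quadratically_with_dt(self, ac_model):
        g = ac_model.make_geometry(np.array([[0.0, 0, 0], [2.3, 0, 0]]))
        drifts = []
        for dt in (0.5, 0.25):
            st = initialize(g, {"kind": "fixed", "n_states": 2}, 0, seed=0)
            traj = run_trajectory(st, ac_model, dt_fs=dt, t_max_fs=50.0)
            drifts.append(traj.total_energy.max() - traj.total_energy.min())
        assert drifts[1] == pytest.approx(drifts[0] / 4, rel=0.3)


class TestElectronicStep:
    def test_uncoupled_populations_constant_phases_advance(self):
        E = np.array([0.1, 0.3])
        vd = np.zeros((2, 2))
        c0 = np.array([np.sqrt(0.7), np.sqrt(0.3)], dtype=complex)
        dt = 10.0
        c = electronic_step(c0, E, E, vd, vd, dt, n_substeps=16)
        np.testing.assert_allclose(np.abs(c) ** 2, np.abs(c0) ** 2, atol=1e-12)
        np.testing.assert_allclose(np.angle(c / c0), -E * dt, atol=1e-10)

    def test_degenerate_rabi_oscillation(self):
        """Two degenerate states with constant coupling kappa exchange
        population as sin^2(kappa t)."""
        E = np.zeros(2)
        kappa = 0.02
        vd = np.array([[0.0, kappa], [-kappa, 0.0]])
        c = np.array([1.0, 0.0], dtype=complex)
        t_total = 30.0
        c = electronic_step(c, E, E, vd, vd, t_total, n_substeps=200)
        assert np.abs(c[1]) ** 2 == pytest.approx(np.sin(kappa * t_total) ** 2,
                                                  abs=1e-8)

    def test_norm_preserved_over_many_substeps(self):
        rng = np.random.default_rng(0)
        E = np.array([0.0, 0.05, 0.11])
        vd = np.zeros((3, 3))
        vd[0, 1] = -0.01
        vd[1, 0] = 0.01
        vd[1, 2] = 0.03
        vd[2, 1] = -0.03
        c = rng.normal(size=3) + 1j * rng.normal(size=3)
        c /= np.linalg.norm(c)
        for _ in range(100):
            c = electronic_step(c, E, E, vd, vd, 20.0, n_substeps=1000)
        assert abs(np.linalg.norm(c) - 1.0) < 1e-8


class TestHopping:
    def test_pure_active_state_never_hops(self):
        c = np.array([0.0, 1.0], dtype=complex)
        vd = np.array([[0.0, 0.5], [-0.5, 0.0]])
        g = hop_probabilities(c, vd, 20.0, active=1)
        np.testing.assert_array_equal(g, 0.0)

    def test_negative_flux_clipped_to_zero(self):
        c = np.array([np.sqrt(0.5), np.sqrt(0.5)], dtype=complex)
        vd = np.array([[0.0, -0.4], [0.4, 0.0]])
        g = hop_probabilities(c, vd, 20.0, active=0)
        assert g[1] == 0.0

    def test_depleted_coefficient_gives_zero_probabilities(self):
        c = np.array([1e-9, 1.0], dtype=complex)
        vd = np.array([[0.0, 0.5], [-0.5, 0.0]])
        np.testing.assert_array_equal(hop_probabilities(c, vd, 20.0, 0), 0.0)

    def test_downhill_hop_conserves_total_energy(self, decay_model):
        g = decay_model.reference_geometry()
        st = initialize(g, {"kind": "fixed", "n_states": 3}, 2, seed=1)
        st.velocities = np.array([[0.002, 0, 0], [-0.002, 0, 0]])
        props = decay_model.evaluate(g)
        st.props = props
        e_before = st.kinetic_energy() + props.energies[2]
        event = attempt_hop(st, np.array([0.0, 1.0, 0.0]), props.energies,
                            props, rescale="full")
        assert event.outcome == "accepted"
        e_after = st.kinetic_energy() + props.energies[st.active]
        assert e_after == pytest.approx(e_before, abs=1e-8)

    def test_energy_forbidden_hop_is_frustrated(self, decay_model):
        g = decay_model.reference_geometry()
        st = initialize(g, {"kind": "fixed", "n_states": 3}, 0, seed=1)
        st.velocities = np.array([[1e-4, 0, 0], [-1e-4, 0, 0]])  # tiny KE
        props = decay_model.evaluate(g)
        st.props = props
        event = attempt_hop(st, np.array([0.0, 0.0, 1.0]), props.energies,
                            props, rescale="full")
        assert event.outcome == "frustrated"
        assert st.active == 0

    def test_no_probability_no_event(self, decay_model):
        g = decay_model.reference_geometry()
        st = initialize(g, {"kind": "fixed", "n_states": 3}, 2, seed=1)
        st.props = decay_model.evaluate(g)
        assert attempt_hop(st, np.zeros(3), st.props.energies, st.props) is None


class TestRescale:
    def test_zero_gap_leaves_velocities(self):
        v = np.array([[0.01, 0, 0], [0.0, 0.002, 0]])
        m = np.array([1000.0, 1500.0])
        np.testing.assert_array_equal(rescale_velocity(v, m, 0.0), v)

    def test_downhill_gains_exact_kinetic_energy(self):
        v = np.array([[0.01, 0, 0], [-0.01, 0, 0]])
        m = np.array([2000.0, 2000.0])
        new_v = rescale_velocity(v, m, -0.01)
        ke_old = 0.5 * np.sum(m[:, None] * v ** 2)
        ke_new = 0.5 * np.sum(m[:, None] * new_v ** 2)
        assert ke_new - ke_old == pytest.approx(0.01, abs=1e-12)

    def test_zero_projection_frustrates_nac_mode(self):
        v = np.array([[0.0, 0.01, 0], [0.0, -0.01, 0]])
        m = np.array([2000.0, 2000.0])
        d = np.array([[1.0, 0, 0], [-1.0, 0, 0]])  # orthogonal to v
        assert rescale_velocity(v, m, 1e-4, direction=d) is None


class TestTrajectories:
    def test_zero_time_yields_single_frame(self, ac_model):
        st = initialize(ac_model.reference_geometry(),
                        {"kind": "fixed", "n_states": 2}, 0, seed=0)
        traj = run_trajectory(st, ac_model, dt_fs=0.5, t_max_fs=0.0)
        assert traj.n_steps == 1

    def test_uncoupled_upper_state_never_decays(self):
        model = AvoidedCrossingModel(coupling=0.0)
        g = model.make_geometry(np.array([[0.0, 0, 0], [2.6, 0, 0]]))
        st = initialize(g, {"kind": "fixed", "n_states": 2}, 1, seed=0)
        traj = run_trajectory(st, model, dt_fs=0.5, t_max_fs=100.0)
        assert np.all(traj.active == 1)
        assert abs(traj.populations[-1, 1] - 1.0) < 1e-8

    def test_electronic_norm_conserved_along_trajectory(self, decay_model):
        g = decay_model.reference_geometry()
        st = initialize(g, {"kind": "fixed", "n_states": 3}, 2, seed=3)
        traj = run_trajectory(st, decay_model, dt_fs=0.5, t_max_fs=100.0)
        assert np.abs(traj.populations.sum(axis=1) - 1.0).max() < 1e-8

    def test_bit_reproducible_for_fixed_seed(self, decay_model):
        g = decay_model.reference_geometry()
        hess = compute_hessian(decay_model, g, state=0)
        spec = {"kind": "wigner", "hessian": hess, "n_states": 3}
        runs = [run_trajectory(initialize(g, spec, 2, seed=17), decay_model,
                               dt_fs=0.5, t_max_fs=50.0) for _ in range(2)]
        np.testing.assert_array_equal(runs[0].positions, runs[1].positions)
        np.testing.assert_array_equal(runs[0].active, runs[1].active)

    def test_population_table_partitions_unity(self, decay_model):
        g = decay_model.reference_geometry()
        spec = {"kind": "fixed", "n_states": 3}
        table, trajs = run_ensemble_of_trajectories(
            lambda s: initialize(g, spec, 2, s), decay_model,
            n_traj=4, dt_fs=0.5, t_max_fs=20.0, seed=0)
        sums = table[["n_0", "n_1", "n_2"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_single_trajectory_populations_are_indicator(self, decay_model):
        g = decay_model.reference_geometry()
        table, _ = run_ensemble_of_trajectories(
            lambda s: initialize(g, {"kind": "fixed", "n_states": 3}, 2, s),
            decay_model, n_traj=1, dt_fs=0.5, t_max_fs=20.0, seed=0)
        vals = table[["n_0", "n_1", "n_2"]].values
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_hop_accounting_and_energy_conservation(self, decay_model):
        g = decay_model.reference_geometry()
        hess = compute_hessian(decay_model, g, state=0)
        spec = {"kind": "wigner", "hessian": hess, "n_states": 3}
        traj = run_trajectory(initialize(g, spec, 2, seed=5), decay_model,
                              dt_fs=0.5, t_max_fs=100.0)
        outcomes = {h.outcome for h in traj.hops}
        assert outcomes <= {"accepted", "frustrated"}
        # every accepted hop conserves KE + E_active across the hop itself
        accepted = [h for h in traj.hops if h.outcome == "accepted"]
        assert accepted
        assert max(h.energy_error for h in accepted) < 1e-8
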