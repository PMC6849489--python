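"""Minimum and MECI optimization, gap statistics and seam scans."""

import numpy as np
import pytest

from photodyn.core import ElectronicProperties, Geometry
from photodyn.critical import (GapStatistics, MeciParams, gap_statistics,
                               optimize_meci, optimize_minimum, seam_scan)
from photodyn.errors import InvalidInputError
from photodyn.models import ConicalIntersectionModel
from photodyn.units import EV_PER_HARTREE


def _internal_distances(geom):
    c = geom.coords
    return np.array([np.linalg.norm(c[0] - c[1]), np.linalg.norm(c[0] - c[2]),
                     np.linalg.norm(c[1] - c[2])])


class _Quadratic:
    """Convex 2-state test surface: quadratic in the pair distances, so it
    shares the rigid-motion invariance of descriptor-based surfaces."""

    n_states = 2

    def __init__(self, target_distances):
        self.targets = dict(target_distances)  # {(a, b): r_ab}

    def evaluate(self, geom):
        c = geom.coords
        e0 = 0.0
        grad = np.zeros_like(c)
        for (a, b), t in self.targets.items():
            diff = c[a] - c[b]
            r = np.linalg.norm(diff)
            e0 += 0.5 * (r - t) ** 2
            g = (r - t) * diff / r
            grad[a] += g
            grad[b] -= g
        grads = np.stack([grad, grad])
        return ElectronicProperties(energies=np.array([e0, e0 + 0.1]),
                                    gradients=grads,
                                    nacs=np.zeros((1, geom.n_atoms, 3)))


class TestOptimizeMinimum:
    def test_quadratic_surface_exact_minimum(self):
        targets = {(0, 1): 2.0, (0, 2): 2.2, (1, 2): 3.1}
        src = _Quadratic(targets)
        start = Geometry(("X", "X", "X"),
                         np.array([[0.0, 0, 0], [2.3, 0.2, 0], [0.1, 2.5, 0]]),
                         np.ones(3))
        res = optimize_minimum(src, 0, start, tol=1e-8)
        assert res.converged
        d = _internal_distances(res.geometry)
        np.testing.assert_allclose(d, [2.0, 2.2, 3.1], atol=1e-6)
        assert res.energies[0] < 1e-12

    def test_model_minimum_matches_grid_search(self):
        # kappa != lam makes the lower-sheet minimum unique (up to x -> -x)
        model = ConicalIntersectionModel(lam=0.02)
        res = optimize_minimum(model, 0, model.reference_geometry(), tol=1e-8)
        # brute-force 1-D oracle: E- = k/2 x^2 - kappa x along the tuning mode
        xs = np.linspace(0.0, 2.5, 25001)
        es = 0.5 * model.k * xs ** 2 - model.kappa * xs
        k_best = int(np.argmin(es))
        d = _internal_distances(res.geometry)
        x_opt = d[0] - model.a
        assert abs(x_opt - xs[k_best]) < 1e-4 + (xs[1] - xs[0])
        assert res.energies[0] == pytest.approx(es[k_best], abs=1e-8)

    def test_start_at_minimum_returns_immediately(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.5, 1.8, 0]])
        start = Geometry(("X", "X", "X"), coords, np.ones(3))
        d = _internal_distances(start)
        src = _Quadratic({(0, 1): d[0], (0, 2): d[1], (1, 2): d[2]})
        res = optimize_minimum(src, 0, start, tol=1e-8)
        assert res.n_iterations == 0
        np.testing.assert_allclose(res.geometry.coords, coords, atol=1e-12)


def _grid_seam_minimum(model, n=81):
    """Brute-force MECI oracle: scan the internal displacements (x, y, z),
    keep near-degenerate points, return the lowest-mean-energy one."""
    span = np.linspace(-0.4, 0.4, n)
    best = None
    for x in span:
        for y in span:
            for z in span:
                gap = 2.0 * np.hypot(model.kappa * x, model.lam * y)
                if gap > 1e-3:
                    continue
                mean = 0.5 * model.k * (x * x + y * y + z * z)
                if best is None or mean < best[3]:
                    best = (x, y, z, mean)
    return best


class TestOptimizeMeci:
    def test_exact_model_meci_matches_grid_oracle(self, ci_model):
        res = optimize_meci(ci_model, (0, 1), ci_model.reference_geometry())
        assert res.converged
        x, y, z, _ = _grid_seam_minimum(ci_model)
        d_opt = _internal_distances(res.geometry)
        d_oracle = np.array([ci_model.a + x, ci_model.b + y, ci_model.c + z])
        assert np.abs(d_opt - d_oracle).max() < 1e-2

    def test_gap_closes_on_exact_model(self, ci_model):
        res = optimize_meci(ci_model, (0, 1), ci_model.reference_geometry())
        assert res.energies[1] - res.energies[0] < 1e-4

    def test_penalty_objective_monotone_over_outer_iterations(self, ci_model):
        res = optimize_meci(ci_model, (0, 1), ci_model.reference_geometry())
        gaps = [entry["gap"] for entry in res.log]
        assert all(b <= a + 1e-12 for a, b in zip(gaps[:-1], gaps[1:]))

    def test_nn_surrogate_gap_positive_but_small(self, ci_nn, ci_model):
        """A smooth surrogate cannot reach exact degeneracy: the optimized
        gap is positive yet below the configured tolerance."""
        params = MeciParams(gap_tol=2e-2)
        res = optimize_meci(ci_nn, (0, 1), ci_model.reference_geometry(),
                            params)
        gap = res.energies[1] - res.energies[0]
        assert 0.0 < gap < params.gap_tol

    def test_invalid_pair_rejected(self, ci_model):
        with pytest.raises(InvalidInputError):
            optimize_meci(ci_model, (1, 0), ci_model.reference_geometry())


class _Shifted:
    """Reference surface with the upper state rigidly shifted by delta."""

    def __init__(self, base, delta):
        self.base = base
        self.delta = delta
        self.n_states = base.n_states

    def evaluate(self, geom):
        props = self.base.evaluate(geom)
        props.energies = props.energies.copy()
        props.energies[1] += self.delta
        return props


class TestGapStatistics:
    def _near_seam_geometries(self, model, n=60, seed=0):
        rng = np.random.default_rng(seed)
        base = model.meci_geometry().coords
        return [model.make_geometry(base + rng.normal(0, 0.05, base.shape))
                for _ in range(n)]

    def test_identical_sources_give_zero_difference(self, ci_model):
        geoms = self._near_seam_geometries(ci_model)
        stats = gap_statistics(geoms, ci_model, ci_model)
        assert stats.count == len(geoms)
        assert stats.mean_difference == pytest.approx(0.0, abs=1e-12)

    def test_constructed_offset_is_recovered_exactly(self, ci_model):
        delta = 0.005  # Hartree
        geoms = self._near_seam_geometries(ci_model)
        stats = gap_statistics(geoms, ci_model, _Shifted(ci_model, delta))
        assert stats.mean_difference == pytest.approx(
            delta * EV_PER_HARTREE, abs=1e-10)

    def test_empty_selection_is_an_error(self, ci_model):
        far = [ci_model.reference_geometry()]  # gap ~0.65 eV off the seam
        with pytest.raises(InvalidInputError):
            gap_statistics(far, ci_model, ci_model, gap_cut_ev=0.1)


class TestSeamScan:
    def test_single_point_at_meci_is_degenerate(self, ci_model):
        meci = ci_model.meci_geometry()
        out = seam_scan(ci_model, meci, np.zeros((3, 3)), np.zeros((3, 3)),
                        [0.0], [0.0])
        e = out["energies"][0, 0]
        assert abs(e[1] - e[0]) < 1e-8

    def test_scan_minimum_gap_sits_at_the_meci(self, ci_model):
        meci = ci_model.meci_geometry()
        da = np.zeros((3, 3))
        da[1, 0] = 1.0   # stretches r12 (the x coordinate)
        db = np.zeros((3, 3))
        db[2, :] = [-0.25 / 2.0, 1.9843 / 2.0, 0.0]  # roughly stretches r13
        grid = np.linspace(-0.2, 0.2, 21)
        out = seam_scan(ci_model, meci, da, db, grid, grid)
        gaps = out["energies"][:, :, 1] - out["energies"][:, :, 0]
        ia, ib = np.unravel_index(np.argmin(gaps), gaps.shape)
        assert abs(grid[ia]) <= 0.021 and abs(grid[ib]) <= 0.021
        assert not out["failures"]

    def test_mirror_symmetry_of_the_model(self, ci_model):
        """Out-of-plane displacement of one atom leaves all pair distances
        even in +/- delta, so the scan is mirror-symmetric."""
        meci = ci_model.meci_geometry()
        da = np.zeros((3, 3))
        da[1, 0] = 1.0
        db = np.zeros((3, 3))
        db[2, 2] = 1.0   # atom 2 out of plane: distances even in +/- delta
        grid_b = np.linspace(-0.3, 0.3, 11)
        out = seam_scan(ci_model, meci, da, db, [0.0], grid_b)
        e = out["energies"][0]
        np.testing.assert_allclose(e, e[::-1], atol=1e-10)
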