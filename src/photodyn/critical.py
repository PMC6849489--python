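"""Optimization of critical points on model or NN surfaces.

State minima are found by gradient descent (L-BFGS on the predicted
energy with its analytic gradient).  Minimum-energy conical intersections
(MECIs) use a penalty formulation that needs only energies and gradients
of the two crossing states — no NAC at the optimizer level:

    F(R) = (E_i + E_j)/2 + sigma * dE^2 / (dE + alpha),   dE = E_j - E_i

The penalty prefactor sigma grows geometrically until the gap falls below
the requested tolerance.  Because an NN surface is smooth everywhere, its
two states cannot actually touch: the optimized "MECI" on a surrogate
retains a small positive gap, which :func:`gap_statistics` quantifies
against the reference surface for near-seam configurations.

Optimization runs in Cartesian coordinates; rigid translations and
rotations are flat directions of any descriptor-based surface and are
projected out of the reported gradient norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import Geometry
from .errors import ConvergenceError, InvalidInputError
from .units import EV_PER_HARTREE


def _trans_rot_projector(geom: Geometry) -> np.ndarray:
    """Projector removing rigid translations and rotations, shape (3N, 3N)."""
    n = geom.n_atoms
    coords = geom.coords - geom.coords.mean(axis=0)
    basis = []
    for x in range(3):
        t = np.zeros((n, 3))
        t[:, x] = 1.0
        basis.append(t.ravel())
    for axis in np.eye(3):
        r = np.cross(np.broadcast_to(axis, (n, 3)), coords)
        basis.append(r.ravel())
    B = np.array(basis).T
    q, _ = np.linalg.qr(B)
    # drop numerically null columns (linear molecules)
    keep = [k for k in range(q.shape[1])
            if np.abs(B.T @ q[:, k]).max() > 1e-10]
    q = q[:, keep]
    return np.eye(3 * n) - q @ q.T


@dataclass
class OptimizationResult:
    geometry: Geometry
    energies: np.ndarray
    grad_norm: float
    n_iterations: int
    converged: bool
    log: list = field(default_factory=list)


def optimize_minimum(surface_source, state: int, geom_start: Geometry,
                     tol: float = 1e-6, max_iterations: int = 500
                     ) -> OptimizationResult:
    """Minimize one adiabatic surface from a starting geometry.

    Converged when the translation/rotation-projected gradient norm of the
    target state falls below ``tol`` (Hartree/Bohr).

    Raises
    ------
    ConvergenceError
        If the iteration budget is exhausted; the last iterate is attached.
    """
    proj = _trans_rot_projector(geom_start)
    shape = geom_start.coords.shape

    def objective(x):
        props = surface_source.evaluate(geom_start.with_coords(x.reshape(shape)))
        return float(props.energies[state]), proj @ props.gradients[state].ravel()

    res = minimize(objective, geom_start.coords.ravel(), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": max_iterations, "gtol": tol * 1e-2,
                            "ftol": 1e-14})
    geom = geom_start.with_coords(res.x.reshape(shape))
    props = surface_source.evaluate(geom)
    gnorm = float(np.linalg.norm(proj @ props.gradients[state].ravel()))
    result = OptimizationResult(geom, props.energies, gnorm, int(res.nit),
                                gnorm < tol)
    if not result.converged:
        raise ConvergenceError(
            f"minimum optimization did not reach |grad| < {tol} "
            f"(final {gnorm:.3e} after {res.nit} iterations)")
    return result


@dataclass
class MeciParams:
    sigma0: float = 3.5
    alpha: float = 0.02          # Hartree, smoothing of the penalty
    sigma_growth: float = 1.5
    gap_tol: float = 1e-4        # Hartree
    max_outer: int = 20
    max_inner: int = 200


def optimize_meci(surface_source, state_pair: tuple[int, int],
                  geom_start: Geometry, penalty_params: MeciParams | None = None,
                  tol: float = 1e-4) -> OptimizationResult:
    """Minimum-energy conical intersection between two adjacent states.

    Minimizes the penalty objective for increasing sigma until the energy
    gap drops below ``gap_tol`` and the seam-projected mean-energy gradient
    norm below ``tol``.  On an NN surrogate the reachable gap is bounded
    below by the surface's smoothness; convergence is then declared on the
    gradient criterion once the gap stops improving.
    """
    i, j = state_pair
    if not (0 <= i < j):
        raise InvalidInputError("state_pair must be (i, j) with i < j")
    p = penalty_params or MeciParams()
    proj = _trans_rot_projector(geom_start)
    shape = geom_start.coords.shape

    def make_objective(sigma):
        def objective(x):
            props = surface_source.evaluate(geom_start.with_coords(x.reshape(shape)))
            ei, ej = props.energies[i], props.energies[j]
            gi = props.gradients[i].ravel()
            gj = props.gradients[j].ravel()
            gap = ej - ei
            mean = 0.5 * (ei + ej)
            # |gap| keeps the penalty repulsive even if a surrogate lets the
            # fitted states cross
            agap = abs(gap)
            pen = gap * gap / (agap + p.alpha)
            f = mean + sigma * pen
            dpen = np.sign(gap) * (gap * gap + 2.0 * p.alpha * agap) \
                / (agap + p.alpha) ** 2
            grad = 0.5 * (gi + gj) + sigma * dpen * (gj - gi)
            return float(f), proj @ grad
        return objective

    x = geom_start.coords.ravel().copy()
    sigma = p.sigma0
    log = []
    total_iters = 0
    best_gap = np.inf
    for outer in range(p.max_outer):
        res = minimize(make_objective(sigma), x, jac=True, method="L-BFGS-B",
                       options={"maxiter": p.max_inner, "gtol": tol * 1e-2,
                                "ftol": 1e-15})
        x = res.x
        total_iters += int(res.nit)
        props = surface_source.evaluate(geom_start.with_coords(x.reshape(shape)))
        gap = float(props.energies[j] - props.energies[i])
        gmean = 0.5 * (props.gradients[i] + props.gradients[j]).ravel()
        # project out the seam-lifting direction (the gap gradient) as well
        dgap = (props.gradients[j] - props.gradients[i]).ravel()
        dgap_p = proj @ dgap
        g_proj = proj @ gmean
        if np.linalg.norm(dgap_p) > 1e-12:
            u = dgap_p / np.linalg.norm(dgap_p)
            g_proj = g_proj - (g_proj @ u) * u
        gnorm = float(np.linalg.norm(g_proj))
        log.append({"outer": outer, "sigma": sigma, "gap": gap,
                    "objective": float(res.fun), "grad_norm": gnorm})
        if gap < p.gap_tol and gnorm < tol:
            geom = geom_start.with_coords(x.reshape(shape))
            return OptimizationResult(geom, props.energies, gnorm,
                                      total_iters, True, log)
        if gap >= best_gap * 0.999 and gnorm < tol:
            # smooth surrogate: the gap has stalled above gap_tol
            break
        best_gap = min(best_gap, gap)
        sigma *= p.sigma_growth
    geom = geom_start.with_coords(x.reshape(shape))
    props = surface_source.evaluate(geom)
    gap = float(props.energies[j] - props.energies[i])
    if gap < p.gap_tol:
        return OptimizationResult(geom, props.energies, gnorm,
                                  total_iters, True, log)
    raise ConvergenceError(
        f"MECI optimization stalled: final gap {gap:.3e} Hartree "
        f"(tol {p.gap_tol:.1e}), final sigma {sigma:.2f}")


@dataclass
class GapStatistics:
    count: int
    mean_difference: float       # surrogate gap - reference gap, eV
    std_difference: float
    ci_low: float                # bootstrap 95% CI on the mean, eV
    ci_high: float
    reference_gaps: np.ndarray
    surrogate_gaps: np.ndarray


def gap_statistics(geometries, reference_source, surrogate_source,
                   state_pair: tuple[int, int] = (0, 1),
                   gap_cut_ev: float = 0.8, n_bootstrap: int = 2000,
                   seed: int = 0) -> GapStatistics:
    """Near-seam gap comparison between a surrogate and its reference.

    Selects the geometries whose *reference* gap is below ``gap_cut_ev``
    (default 0.8 eV) and reports the mean signed difference
    surrogate - reference with a bootstrap confidence interval, both in eV.
    """
    i, j = state_pair
    ref, sur = [], []
    for g in geometries:
        e_ref = reference_source.evaluate(g).energies
        gap_ref = (e_ref[j] - e_ref[i]) * EV_PER_HARTREE
        if gap_ref < gap_cut_ev:
            e_sur = surrogate_source.evaluate(g).energies
            ref.append(gap_ref)
            sur.append((e_sur[j] - e_sur[i]) * EV_PER_HARTREE)
    if not ref:
        raise InvalidInputError(
            f"no geometries with reference gap below {gap_cut_ev} eV")
    ref = np.array(ref)
    sur = np.array(sur)
    diff = sur - ref
    rng = np.random.default_rng(seed)
    means = np.array([
        diff[rng.integers(0, len(diff), len(diff))].mean()
        for _ in range(n_bootstrap)])
    lo, hi = np.percentile(means, [2.5, 97.5])
    return GapStatistics(len(diff), float(diff.mean()), float(diff.std()),
                         float(lo), float(hi), ref, sur)


def seam_scan(surface_source, center_geom: Geometry,
              direction_a: np.ndarray, direction_b: np.ndarray,
              grid_a, grid_b) -> dict:
    """Tabulate all state energies on a 2-D displacement grid.

    ``direction_a``/``direction_b`` are Cartesian displacement patterns
    (N, 3); the grid values are multiples of them applied to the centre
    geometry.  Failed evaluations are recorded and the scan continues.
    """
    da = np.asarray(direction_a, dtype=float)
    db = np.asarray(direction_b, dtype=float)
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    n_states = surface_source.n_states
    energies = np.full((len(grid_a), len(grid_b), n_states), np.nan)
    failures = []
    for ia, a in enumerate(grid_a):
        for ib, b in enumerate(grid_b):
            geom = center_geom.with_coords(center_geom.coords + a * da + b * db)
            try:
                energies[ia, ib] = surface_source.evaluate(geom).energies
            except Exception as exc:  # recorded, scan continues
                failures.append((ia, ib, str(exc)))
    return {"grid_a": grid_a, "grid_b": grid_b, "energies": energies,
            "failures": failures}
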